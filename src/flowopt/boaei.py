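"""Closed-loop Bayesian optimization with adaptive expected improvement.

The campaign loop mirrors an autonomous self-optimizing flow platform:

1. a seeded Latin hypercube of ``2n + 1`` initial experiments;
2. fit the GP surrogate, propose the next conditions by maximizing an
   expected-improvement (EI) acquisition whose exploration offset ``xi``
   adapts geometrically — shrinking after an experiment improves the best
   observed yield (exploit) and growing during stagnation (explore);
3. a standard-condition monitoring run every ``monitoring_interval``
   optimization experiments to track catalyst deactivation (recorded but
   never used to train the surrogate, and not counted as an optimization
   experiment);
4. anomaly rejection: a blank HPLC result (failed gas-liquid separation),
   or a near-zero yield where the model confidently expects a real one, is
   discounted and the same conditions are repeated;
5. termination on a yield plateau (no improvement beyond ``plateau_delta``
   over the last ``plateau_window`` optimization experiments), on low model
   uncertainty (optional), or on budget exhaustion.

The adaptive-xi law is this package's own concrete schedule for the
"dynamic exploration/exploitation" behaviour the original BOAEI algorithm
is described with; the published sources do not state the update rule.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm, qmc

from .design_space import DesignSpace, lhs_design
from .surrogate import GPSurrogate, ImportanceRanking
from .virtual_rig import (CatalystState, DeactivationSchedule, Measurement,
                          NoiseModel, VirtualRig, simulate_step1)

__all__ = [
    "AcquisitionConfig",
    "CampaignConfig",
    "ExperimentRecord",
    "CampaignResult",
    "OSATResult",
    "expected_improvement",
    "adapt_xi",
    "propose",
    "should_terminate",
    "run_campaign",
    "run_osat",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Adaptive-EI schedule (xi in standardized objective units)."""

    xi0: float = 0.05
    xi_min: float = 0.005
    xi_max: float = 0.5
    adapt_up: float = 1.5
    adapt_down: float = 0.7
    improve_delta: float = 0.005  # objective units; same default as plateau

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi_min <= self.xi0 <= self.xi_max:
            raise ValueError("need 0 <= xi_min <= xi0 <= xi_max")
        if not (self.adapt_up >= 1.0 >= self.adapt_down > 0.0):
            raise ValueError("need adapt_up >= 1 >= adapt_down > 0")


@dataclass(frozen=True)
class CampaignConfig:
    """Budget, monitoring cadence and termination rules for one campaign."""

    budget: int = 25  # max optimization experiments, LHS included
    monitoring_interval: int = 4
    plateau_window: int = 5
    plateau_delta: float = 0.005
    sd_threshold: float | None = None
    seed: int = 0
    max_repeats: int = 3  # cap on anomaly-triggered repeats of one condition

    def __post_init__(self) -> None:
        if self.monitoring_interval < 2:
            raise ValueError("monitoring_interval must be at least 2")
        if self.plateau_window < 1 or self.plateau_delta < 0:
            raise ValueError("invalid plateau termination settings")

    def validate_budget(self, n_vars: int) -> None:
        if self.budget < 2 * n_vars + 1:
            raise ValueError(
                f"budget {self.budget} below the {2 * n_vars + 1} LHS "
                f"experiments of a {n_vars}-variable campaign")


@dataclass(frozen=True)
class ExperimentRecord:
    """One executed experiment (optimization, monitoring or rejected)."""

    index: int                      # contiguous over all records
    kind: str                       # lhs | refinement | monitoring | rejected
    opt_index: int | None           # 1-based optimization-experiment counter
    conditions: dict[str, float]
    measurement: Measurement
    objective: float | None         # campaign objective (None if rejected)
    activity: float                 # catalyst activity during the run
    time_on_stream: float           # h, at the start of the run
    xi: float | None = None         # acquisition offset behind this proposal
    proposal_ei: float | None = None


@dataclass(frozen=True)
class CampaignResult:
    """Outcome of one closed-loop campaign."""

    records: tuple[ExperimentRecord, ...]
    best_conditions: dict[str, float]
    best_yield: float
    experiments_to_optimum: int
    termination_reason: str
    importance: ImportanceRanking | None
    seed: int
    mode: str

    @property
    def optimization_records(self) -> tuple[ExperimentRecord, ...]:
        return tuple(r for r in self.records if r.kind in ("lhs", "refinement"))

    @property
    def n_optimization(self) -> int:
        return len(self.optimization_records)

    def to_frame(self) -> pd.DataFrame:
        """One row per record: the campaign's experiment log."""
        rows = []
        for r in self.records:
            row = {"index": r.index, "kind": r.kind, "opt_index": r.opt_index}
            row.update(r.conditions)
            row.update({
                "yield_step1": r.measurement.yield_step1,
                "yield_step2": r.measurement.yield_step2,
                "blank_flag": r.measurement.blank_flag,
                "objective": r.objective,
                "activity": r.activity,
                "time_on_stream": r.time_on_stream,
                "xi": r.xi,
                "proposal_ei": r.proposal_ei,
            })
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "seed": self.seed,
            "best_conditions": self.best_conditions,
            "best_yield": self.best_yield,
            "experiments_to_optimum": self.experiments_to_optimum,
            "termination_reason": self.termination_reason,
            "n_optimization": self.n_optimization,
            "records": self.to_frame().to_dict(orient="records"),
        }
        if self.importance is not None:
            d["importance"] = asdict(self.importance)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=float, **kwargs)


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------


def expected_improvement(mu, sd, best_y: float, xi: float = 0.0):
    """Closed-form EI for maximization: E[max(Y - best - xi, 0)].

    Vectorized over ``mu``/``sd``; at ``sd == 0`` reduces to
    ``max(0, mu - best - xi)``.
    """
    if xi < 0:
        raise ValueError("xi must be nonnegative")
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    delta = mu - best_y - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, delta / np.where(sd > 0, sd, 1.0), 0.0)
    ei = np.where(sd > 0,
                  delta * norm.cdf(z) + sd * norm.pdf(z),
                  np.maximum(delta, 0.0))
    return ei if ei.ndim else float(ei)


def adapt_xi(config: AcquisitionConfig, history: Sequence[bool]) -> float:
    """Fold the improvement history into the next exploration offset.

    ``history`` holds one boolean per past refinement experiment: True if it
    improved the incumbent best by more than ``improve_delta``.  Empty
    history returns ``xi0``; improvements shrink xi by ``adapt_down``,
    stagnation grows it by ``adapt_up``, clipped to ``[xi_min, xi_max]``.

    The schedule is cyclic: a stagnation step that would push xi past
    ``xi_max`` wraps it around to ``xi_min``.  A pure ratchet would park a
    stagnating campaign at maximum exploration for good; wrapping turns
    sustained stagnation into alternating exploration bursts and
    exploitation phases, which is what lets short campaigns polish an
    incumbent optimum instead of burning the remaining budget on corners.
    """
    xi = config.xi0
    for improved in history:
        if improved:
            xi = max(xi * config.adapt_down, config.xi_min)
        elif xi * config.adapt_up > config.xi_max:
            xi = config.xi_min
        else:
            xi = xi * config.adapt_up
    return float(np.clip(xi, config.xi_min, config.xi_max))


def _ei_of(model: GPSurrogate, U: np.ndarray, best_std: float, xi: float):
    mu, sd = model.predict(U, standardized=True)
    return expected_improvement(mu, sd, best_std, xi)


def propose(model: GPSurrogate, space: DesignSpace, best_y: float, xi: float,
            seed: int, n_starts: int = 64,
            ) -> tuple[np.ndarray, float, bool]:
    """Maximize EI by seeded multistart local search on the unit cube.

    Starts are 32 uniform draws plus 32 Gaussian perturbations of the
    incumbent best training point.  Near-equal maxima (within 1e-9 of the
    best EI) are tie-broken toward the smallest unit-scaled lexicographic
    point.  If the whole acquisition surface is numerically zero, the
    proposal falls back to the maximum-posterior-sd point (pure
    exploration) and the returned flag is True.

    Returns ``(conditions in physical units, EI value, fallback_flag)``.
    """
    rng = np.random.default_rng(int(seed))
    n = space.n
    best_std = (best_y - model.y_mean) / model.y_std
    half = n_starts // 2
    x_inc, _ = model.incumbent()
    starts = np.vstack([
        rng.uniform(size=(n_starts - half, n)),
        np.clip(x_inc + rng.normal(scale=0.1, size=(half, n)), 0.0, 1.0),
    ])

    def neg_ei(u):
        return -float(_ei_of(model, u[None, :], best_std, xi)[0])

    candidates = [starts]
    for x0 in starts:
        res = minimize(neg_ei, x0, method="L-BFGS-B",
                       bounds=[(0.0, 1.0)] * n)
        candidates.append(np.clip(res.x, 0.0, 1.0)[None, :])
    cand = np.vstack(candidates)
    ei = np.asarray(_ei_of(model, cand, best_std, xi))
    best_ei = float(ei.max())

    fallback = best_ei < 1e-12
    if fallback:
        # Acquisition numerically flat: pure exploration at maximum sd.
        probe = np.vstack([cand, qmc.Sobol(n, seed=rng).random_base2(9)])
        _, sd = model.predict(probe, standardized=True)
        order = np.lexsort(probe.T[::-1])
        probe, sd = probe[order], sd[order]
        u_best = probe[int(np.argmax(sd))]
        return space.from_unit(u_best), best_ei, True

    near = cand[ei >= best_ei - 1e-9]
    order = np.lexsort(near.T[::-1])  # lexicographic by first variable first
    u_best = near[order[0]]
    return space.from_unit(u_best), best_ei, False


def should_terminate(history: Sequence[float], config: CampaignConfig,
                     n_init: int, model: GPSurrogate | None = None,
                     seed: int = 0) -> tuple[bool, str | None]:
    """Decide whether the campaign should stop, and why.

    ``history`` holds the measured objectives of all optimization
    experiments so far (LHS first).  Rules, in order: budget reached;
    plateau (the best value did not improve by more than ``plateau_delta``
    over the last ``plateau_window`` optimization experiments, never fired
    before the LHS plus a full window is complete); posterior-uncertainty
    stop when ``sd_threshold`` is set and the maximum posterior sd over a
    1024-point seeded sample falls below it.
    """
    history = list(history)
    if len(history) < n_init:
        return False, None
    if len(history) >= config.budget:
        return True, "budget"
    w = config.plateau_window
    if len(history) >= n_init + w:
        best_before = max(history[:-w])
        if max(history) - best_before <= config.plateau_delta:
            return True, "plateau"
    if config.sd_threshold is not None and model is not None:
        sample = qmc.Sobol(model.X.shape[1], seed=int(seed)).random_base2(10)
        _, sd = model.predict(sample)
        if float(sd.max()) < config.sd_threshold:
            return True, "uncertainty"
    return False, None


# ---------------------------------------------------------------------------
# campaign runner
# ---------------------------------------------------------------------------


def run_campaign(rig: VirtualRig, space: DesignSpace,
                 config: CampaignConfig = CampaignConfig(),
                 acq: AcquisitionConfig = AcquisitionConfig(),
                 ) -> CampaignResult:
    """Execute one closed-loop campaign against a (virtual) rig.

    Fully reproducible: all randomness flows from ``config.seed`` (LHS,
    surrogate restarts, proposal starts) and the rig's own seed
    (measurement noise).
    """
    config.validate_budget(space.n)
    ss = np.random.SeedSequence(int(config.seed))
    lhs_seed, fit_entropy, prop_entropy, term_entropy = ss.generate_state(4)

    records: list[ExperimentRecord] = []
    opt_records: list[ExperimentRecord] = []
    xi_flags: list[bool] = []
    monitor_cond = space.as_dict(space.midpoint())
    model: GPSurrogate | None = None

    def execute(cond: Mapping[str, float], kind: str, xi=None, ei=None
                ) -> ExperimentRecord:
        """Run conditions, discounting anomalies and repeating them."""
        for attempt in range(config.max_repeats + 1):
            meas, cat = rig.run_experiment(cond)
            y = rig.objective(meas)
            suspicious = meas.blank_flag
            if model is not None and not suspicious and y < 0.02:
                mu, _ = model.predict(space.to_unit(space.from_dict(cond)))
                suspicious = float(mu[0]) > 0.10
            if suspicious and kind != "monitoring" and attempt < config.max_repeats:
                records.append(ExperimentRecord(
                    index=len(records) + 1, kind="rejected", opt_index=None,
                    conditions=dict(cond), measurement=meas, objective=None,
                    activity=cat.activity, time_on_stream=cat.time_on_stream,
                    xi=xi, proposal_ei=ei))
                continue
            rec = ExperimentRecord(
                index=len(records) + 1, kind=kind,
                opt_index=(len(opt_records) + 1
                           if kind in ("lhs", "refinement") else None),
                conditions=dict(cond), measurement=meas,
                objective=y if kind != "rejected" else None,
                activity=cat.activity, time_on_stream=cat.time_on_stream,
                xi=xi, proposal_ei=ei)
            records.append(rec)
            return rec
        raise AssertionError("unreachable")  # pragma: no cover

    def run_opt(cond, kind, xi=None, ei=None):
        rec = execute(cond, kind, xi, ei)
        opt_records.append(rec)
        if len(opt_records) % config.monitoring_interval == 0:
            execute(monitor_cond, "monitoring")
        return rec

    # -- initial design ---------------------------------------------------
    for x in lhs_design(space, lhs_seed):
        run_opt(space.as_dict(x), "lhs")

    n_init = 2 * space.n + 1

    def train_data():
        recs = [r for r in opt_records]
        # Training-set hygiene: only accepted optimization experiments.
        assert all(r.kind in ("lhs", "refinement") for r in recs)
        U = np.vstack([space.to_unit(space.from_dict(r.conditions))
                       for r in recs])
        ys = np.array([r.objective for r in recs])
        return U, ys

    # -- refinement loop --------------------------------------------------
    reason = "budget"
    it = 0
    while True:
        history = [r.objective for r in opt_records]
        U, ys = train_data()
        model = GPSurrogate.fit(U, ys, seed=int(fit_entropy) + it)
        stop, why = should_terminate(history, config, n_init, model,
                                     seed=int(term_entropy) + it)
        if stop:
            reason = why
            break
        best_y = float(np.max(ys))
        xi = adapt_xi(acq, xi_flags)
        x_phys, ei, _ = propose(model, space, best_y, xi,
                                seed=int(prop_entropy) + it)
        rec = run_opt(space.as_dict(x_phys), "refinement", xi=xi, ei=ei)
        xi_flags.append(rec.objective > best_y + acq.improve_delta)
        it += 1

    # -- results ----------------------------------------------------------
    ys = np.array([r.objective for r in opt_records])
    i_best = int(np.argmax(ys))
    best = float(ys[i_best])
    eto = int(np.argmax(ys >= best - 0.01)) + 1
    return CampaignResult(
        records=tuple(records),
        best_conditions=dict(opt_records[i_best].conditions),
        best_yield=best,
        experiments_to_optimum=eto,
        termination_reason=reason,
        importance=model.importance(space) if model is not None else None,
        seed=config.seed,
        mode=rig.mode,
    )


@dataclass(frozen=True)
class OSATResult:
    """One-step-at-a-time study: step-1 campaign, then step 2 on the IM."""

    step1: CampaignResult
    step2_im: CampaignResult
    im_feed: "object"  # StreamComposition of the reservoir

    @property
    def combined_experiments(self) -> int:
        return (self.step1.experiments_to_optimum
                + self.step2_im.experiments_to_optimum)


def run_osat(params, osat_preset, step1_space: DesignSpace,
             step2_space: DesignSpace,
             noise: NoiseModel = NoiseModel(),
             schedule: DeactivationSchedule = DeactivationSchedule(),
             config1: CampaignConfig = CampaignConfig(budget=25),
             config2: CampaignConfig = CampaignConfig(budget=25),
             seed: int = 0) -> OSATResult:
    """Optimize the two steps sequentially, as on the physical platform.

    The step-1 campaign runs first; its best measured conditions define the
    intermediate-mixture reservoir (the noise-free step-1 outlet at those
    conditions with fresh catalyst, a 2:1 mixture of roughly 65:35).  The
    step-2 campaign then optimizes consumption of the aminophenol in that
    reservoir.
    """
    ss = np.random.SeedSequence(int(seed))
    s_rig1, s_c1, s_rig2, s_c2 = (int(v) for v in ss.generate_state(4))
    rig1 = VirtualRig("step1", params, osat_preset, noise, schedule,
                      seed=s_rig1)
    res1 = run_campaign(rig1, step1_space,
                        config=_reseed(config1, s_c1))
    feed = simulate_step1(res1.best_conditions, CatalystState(), params,
                          osat_preset)
    rig2 = VirtualRig("step2_im", params, osat_preset, noise, schedule,
                      seed=s_rig2, feed=feed)
    res2 = run_campaign(rig2, step2_space, config=_reseed(config2, s_c2))
    return OSATResult(step1=res1, step2_im=res2, im_feed=feed)


def _reseed(config: CampaignConfig, seed: int) -> CampaignConfig:
    from dataclasses import replace
    return replace(config, seed=int(seed) % (2**31))
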