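"""Study configuration, validation and the reproducible end-to-end driver.

A study bundle reruns the whole comparison on the virtual rig: the step-1
campaign, the step-2 campaign on the pure reservoir and on the
intermediate mixture, and the telescoped campaign, all from one global
seed.  The seed deterministically spawns independent per-campaign and
per-measurement streams, so each campaign is also individually
reproducible.  Every output file embeds the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .boaei import (AcquisitionConfig, CampaignConfig, CampaignResult,
                    run_campaign)
from .design_space import DesignSpace
from .green_metrics import comparison_report, mass_flows, reference_report
from .presets import (DESIGN_SPACE_FOR_MODE, RIG_FOR_MODE,
                      design_space_preset, kinetic_preset, rig_preset)
from .virtual_rig import (CatalystState, DeactivationSchedule, NoiseModel,
                          VirtualRig, intermediate_mixture_feed,
                          pure_aminophenol_feed, simulate_step1,
                          simulate_step2, simulate_telescoped)

__all__ = ["ConfigError", "StudyConfig", "validate_config", "load_config",
           "run_study"]

_CAMPAIGN_KEYS = {"budget", "monitoring_interval", "plateau_window",
                  "plateau_delta", "sd_threshold"}
_NOISE_KEYS = {"sigma_abs", "p_fault"}
_TOP_KEYS = {"seed", "output_dir", "kinetics", "noise", "campaign",
             "budgets"}

_DEFAULT_BUDGETS = {"step1": 25, "step2": 25, "step2_im": 25,
                    "telescoped": 18}


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid study config:\n  - " + "\n  - ".join(errors))


@dataclass(frozen=True)
class StudyConfig:
    """Normalized configuration of a full comparison study."""

    seed: int = 0
    output_dir: str = "runs/study"
    kinetics: str = "paper"
    noise: NoiseModel = NoiseModel()
    campaign: dict = field(default_factory=dict)  # overrides for all modes
    budgets: dict = field(default_factory=lambda: dict(_DEFAULT_BUDGETS))

    def canonical(self) -> dict:
        d = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "kinetics": self.kinetics,
            "noise": {"sigma_abs": self.noise.sigma_abs,
                      "p_fault": self.noise.p_fault},
            "campaign": dict(sorted(self.campaign.items())),
            "budgets": dict(sorted(self.budgets.items())),
        }
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(raw: Mapping[str, Any] | None) -> StudyConfig:
    """Check a raw mapping and return the normalized config.

    Unknown keys are rejected with their location; all errors are
    aggregated into a single :class:`ConfigError`.
    """
    errors: list[str] = []
    raw = dict(raw or {})
    if not raw:
        errors.append("empty config: required keys are "
                      + ", ".join(sorted(_TOP_KEYS)))
        raise ConfigError(errors)
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown key {key!r} at top level")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        errors.append("seed: must be an integer")
        seed = 0

    noise_raw = raw.get("noise", {})
    noise = NoiseModel()
    if not isinstance(noise_raw, Mapping):
        errors.append("noise: must be a mapping")
    else:
        for key in noise_raw:
            if key not in _NOISE_KEYS:
                errors.append(f"unknown key {key!r} in noise")
        try:
            noise = NoiseModel(**{k: v for k, v in noise_raw.items()
                                  if k in _NOISE_KEYS})
        except (TypeError, ValueError) as exc:
            errors.append(f"noise: {exc}")

    campaign = raw.get("campaign", {})
    if not isinstance(campaign, Mapping):
        errors.append("campaign: must be a mapping")
        campaign = {}
    else:
        for key in campaign:
            if key not in _CAMPAIGN_KEYS:
                errors.append(f"unknown key {key!r} in campaign")
        campaign = {k: v for k, v in campaign.items() if k in _CAMPAIGN_KEYS}

    budgets = dict(_DEFAULT_BUDGETS)
    budgets_raw = raw.get("budgets", {})
    if not isinstance(budgets_raw, Mapping):
        errors.append("budgets: must be a mapping")
    else:
        for mode, value in budgets_raw.items():
            if mode not in _DEFAULT_BUDGETS:
                errors.append(f"unknown mode {mode!r} in budgets")
            elif not isinstance(value, int) or value < 1:
                errors.append(f"budgets.{mode}: must be a positive integer")
            else:
                budgets[mode] = value

    kinetics = raw.get("kinetics", "paper")
    try:
        kinetic_preset(kinetics)
    except KeyError as exc:
        errors.append(f"kinetics: {exc.args[0]}")

    # preset cross-checks (bounds sanity of every referenced design space)
    for mode, name in DESIGN_SPACE_FOR_MODE.items():
        try:
            design_space_preset(name)
        except Exception as exc:  # pragma: no cover - corrupt install only
            errors.append(f"design space {name!r}: {exc}")

    if errors:
        raise ConfigError(errors)
    return StudyConfig(seed=seed, output_dir=str(raw.get("output_dir",
                                                         "runs/study")),
                       kinetics=kinetics, noise=noise,
                       campaign=dict(campaign), budgets=budgets)


def load_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _campaign_config(cfg: StudyConfig, mode: str, seed: int) -> CampaignConfig:
    kwargs = dict(cfg.campaign)
    kwargs.setdefault("budget", cfg.budgets[mode])
    return CampaignConfig(seed=int(seed) % (2**31), **kwargs)


def make_rig(mode: str, cfg: StudyConfig, seed: int,
             feed=None) -> tuple[VirtualRig, DesignSpace]:
    """Construct the rig and design space for one campaign mode."""
    params = kinetic_preset(cfg.kinetics)
    preset = rig_preset(RIG_FOR_MODE[mode])
    space = design_space_preset(DESIGN_SPACE_FOR_MODE[mode])
    rig = VirtualRig(mode, params, preset, noise=cfg.noise,
                     seed=int(seed) % (2**31), feed=feed)
    return rig, space


def run_study(cfg: StudyConfig) -> dict[str, Any]:
    """Execute the full comparison and write the study bundle.

    Returns a manifest dict with per-mode campaign results, the rig-based
    comparison table, the reference comparison table computed from the
    published row inputs, and the importance summaries.  Idempotent for a
    fixed config: identical configs produce identical bundles.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(8)

    params = kinetic_preset(cfg.kinetics)
    osat_preset = rig_preset("osat")
    tel_preset = rig_preset("telescoped")
    step1_space = design_space_preset("step1")

    results: dict[str, CampaignResult] = {}
    errors: dict[str, str] = {}

    def run_mode(mode, seed_rig, seed_camp, feed=None):
        try:
            rig, space = make_rig(mode, cfg, seed_rig, feed=feed)
            results[mode] = run_campaign(
                rig, space, config=_campaign_config(cfg, mode, seed_camp))
        except Exception as exc:
            errors[mode] = f"{type(exc).__name__}: {exc}"

    run_mode("step1", seeds[0], seeds[1])

    # reservoirs for the step-2 campaigns
    im_feed = None
    if "step1" in results:
        im_feed = simulate_step1(results["step1"].best_conditions,
                                 CatalystState(), params, osat_preset)
    pure_feed = pure_aminophenol_feed(
        im_feed.c_aminophenol if im_feed is not None else 0.01625, params)
    run_mode("step2", seeds[2], seeds[3], feed=pure_feed)
    if im_feed is not None:
        run_mode("step2_im", seeds[4], seeds[5], feed=im_feed)
    run_mode("telescoped", seeds[6], seeds[7])

    # -- green metrics at the campaign optima -----------------------------
    entries = {}
    if "step1" in results:
        r = results["step1"]
        outlet = simulate_step1(r.best_conditions, CatalystState(), params,
                                osat_preset)
        entries["osat_step1"] = (
            mass_flows(r.best_conditions, osat_preset, outlet, "step1"),
            r.experiments_to_optimum)
    if "step2_im" in results and im_feed is not None:
        r = results["step2_im"]
        outlet = simulate_step2(im_feed, r.best_conditions, params,
                                osat_preset)
        entries["osat_step2"] = (
            mass_flows(r.best_conditions, osat_preset, outlet, "step2_im",
                       feed=im_feed),
            r.experiments_to_optimum)
    if {"osat_step1", "osat_step2"} <= entries.keys():
        bd1, n1 = entries["osat_step1"]
        bd2, n2 = entries["osat_step2"]
        combined = type(bd1)(bd1.materials + bd2.materials,
                             bd2.product_rate_g_h)
        entries["osat_combined"] = (combined, n1 + n2)
    if "telescoped" in results:
        r = results["telescoped"]
        _, out2 = simulate_telescoped(r.best_conditions, CatalystState(),
                                      params, tel_preset)
        entries["telescoped"] = (
            mass_flows(r.best_conditions, tel_preset, out2, "telescoped"),
            r.experiments_to_optimum)

    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = comparison_report(entries)
    reference = reference_report()

    # -- write the bundle --------------------------------------------------
    stamp = {"config_hash": cfg.config_hash, "seed": cfg.seed}
    for mode, res in results.items():
        frame = res.to_frame()
        for key, val in stamp.items():
            frame[key] = val
        frame.to_csv(out / f"{mode}_experiments.csv", index=False)
        payload = res.to_dict() | stamp
        (out / f"{mode}_campaign.json").write_text(
            json.dumps(payload, default=float, indent=1))
    for name, frame in (("comparison", table), ("comparison_reference",
                                                reference)):
        frame = frame.copy()
        for key, val in stamp.items():
            frame[key] = val
        frame.to_csv(out / f"{name}.csv", index=False)
        (out / f"{name}.txt").write_text(
            frame.to_string(index=False) + "\n")
    importance = {mode: res.to_dict().get("importance")
                  for mode, res in results.items()}
    (out / "importance.json").write_text(
        json.dumps(importance | {"_stamp": stamp}, default=float, indent=1))
    manifest = {
        "config": cfg.canonical(),
        **stamp,
        "campaigns": {m: {"best_yield": r.best_yield,
                          "experiments_to_optimum": r.experiments_to_optimum,
                          "termination_reason": r.termination_reason}
                      for m, r in results.items()},
        "errors": errors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"results": results, "comparison": table, "reference": reference,
            "manifest": manifest, "output_dir": str(out)}
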