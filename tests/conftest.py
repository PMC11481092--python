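"""Shared fixtures: calibrated presets and batches of seeded campaigns.

The campaign batches are session-scoped because several tests (optimizer
efficiency, single-step vs telescoped comparison, importance ranking) read
different statistics from the same runs.
"""

import numpy as np
import pytest

from flowopt import boaei, presets, virtual_rig as vr


@pytest.fixture(scope="session")
def paper_params():
    return presets.kinetic_preset("paper")


@pytest.fixture(scope="session")
def osat_preset():
    return presets.rig_preset("osat")


@pytest.fixture(scope="session")
def tel_preset():
    return presets.rig_preset("telescoped")


@pytest.fixture(scope="session")
def step1_space():
    return presets.design_space_preset("step1")


@pytest.fixture(scope="session")
def step2_space():
    return presets.design_space_preset("step2-im")


@pytest.fixture(scope="session")
def tel_space():
    return presets.design_space_preset("telescoped")


@pytest.fixture(scope="session")
def im_feed(paper_params, osat_preset, step1_space):
    """Intermediate-mixture reservoir from the calibrated step-1 optimum."""
    return vr.intermediate_mixture_feed(paper_params, osat_preset,
                                        step1_space, n=41)


_CAMPAIGN_NOISE = vr.NoiseModel(sigma_abs=0.01, p_fault=0.0)


@pytest.fixture(scope="session")
def telescoped_campaigns(paper_params, tel_preset, tel_space):
    """20 seeded telescoped campaigns at 1 % measurement noise, budget 18."""
    out = []
    for seed in range(1, 21):
        rig = vr.VirtualRig("telescoped", paper_params, tel_preset,
                            noise=_CAMPAIGN_NOISE, seed=seed + 1000)
        out.append(boaei.run_campaign(
            rig, tel_space, boaei.CampaignConfig(budget=18, seed=seed)))
    return out


@pytest.fixture(scope="session")
def step1_campaigns(paper_params, osat_preset, step1_space):
    """20 seeded step-1 campaigns at 1 % measurement noise, budget 25."""
    out = []
    for seed in range(1, 21):
        rig = vr.VirtualRig("step1", paper_params, osat_preset,
                            noise=_CAMPAIGN_NOISE, seed=seed + 2000)
        out.append(boaei.run_campaign(
            rig, step1_space, boaei.CampaignConfig(budget=25, seed=seed)))
    return out


@pytest.fixture(scope="session")
def step2_im_campaigns(paper_params, osat_preset, step2_space, im_feed):
    """20 seeded step-2 campaigns on the intermediate mixture, budget 25."""
    out = []
    for seed in range(1, 21):
        rig = vr.VirtualRig("step2_im", paper_params, osat_preset,
                            noise=_CAMPAIGN_NOISE, seed=seed + 3000,
                            feed=im_feed)
        out.append(boaei.run_campaign(
            rig, step2_space, boaei.CampaignConfig(budget=25, seed=seed)))
    return out
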