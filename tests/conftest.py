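"""Shared fixtures: default truths and simulated studies used across tests."""

import numpy as np
import pytest

import tscm_kinetics as tk


@pytest.fixture(scope="session")
def saliva_truth():
    return tk.default_saliva_truth()


@pytest.fixture(scope="session")
def monocyte_truth():
    return tk.default_monocyte_truth()


@pytest.fixture(scope="session")
def truth_d():
    return tk.default_truth("D")


@pytest.fixture(scope="session")
def design():
    return tk.StudyDesign(master_seed=0)


@pytest.fixture(scope="session")
def noiseless_design():
    return tk.StudyDesign(
        label_noise_sd=0.0,
        saliva_noise_sd=0.0,
        monocyte_noise_sd=0.0,
        yfv_lognorm_sigma=0.0,
        telomere_noise_sd_bp=0.0,
        master_seed=0,
    )


@pytest.fixture(scope="session")
def study_d(truth_d, saliva_truth, monocyte_truth, design):
    """One noisy simulated model-D study, calibrated, plus shared data."""
    bundle = tk.generate_study("D", truth_d, saliva_truth, monocyte_truth,
                               design, seed=0)
    aux = tk.generate_aux_data(truth_d, design, seed=0)
    return tk.calibrate_bundle(bundle), aux


@pytest.fixture(scope="session")
def noiseless_study_d(truth_d, saliva_truth, monocyte_truth, noiseless_design):
    """A noise-free study: observations lie exactly on the forward model."""
    bundle = tk.generate_study("D", truth_d, saliva_truth, monocyte_truth,
                               noiseless_design, seed=0)
    aux = tk.generate_aux_data(truth_d, noiseless_design, seed=0)
    return tk.calibrate_bundle(bundle), aux


def random_feasible_params(model_id, rng):
    """Draw a random feasible parameter set for one lineage model."""
    base = dict(
        p_N=10.0 ** rng.uniform(-5, -2.5),
        p_1=10.0 ** rng.uniform(-5, -2.5),
        p_2=10.0 ** rng.uniform(-5, -2.5),
        R_1=10.0 ** rng.uniform(-2, -0.5),
        R_2=10.0 ** rng.uniform(-2.5, -1),
        A=0.03,
    )
    if model_id == "A":
        return tk.KineticParams(model_id="A", **base)
    if model_id == "B":
        return tk.KineticParams(
            model_id="B",
            dstar_N=10.0 ** rng.uniform(-5, -2.5),
            dstar_1=10.0 ** rng.uniform(-5, -2.5),
            dstar_2=10.0 ** rng.uniform(-5, -2.5),
            **base,
        )
    k = rng.uniform(0.0, 12.0)
    # keep the equilibrium-implied loss rates non-negative:
    # delta_N <= p_N, and for D/E the burst flux must cover delta_1
    delta_N = base["p_N"] * rng.uniform(0.0, 1.0)
    if model_id == "C":
        return tk.KineticParams(model_id="C", delta_N=delta_N, k=k,
                                frac=rng.uniform(0, 1), **base)
    if model_id == "D":
        cap = base["p_1"] + delta_N * 2.0**k / base["R_1"]
        return tk.KineticParams(model_id="D", delta_N=delta_N,
                                delta_1=cap * rng.uniform(0.0, 0.95), k=k, **base)
    cap = base["p_2"] + delta_N * 2.0**k / base["R_2"]
    return tk.KineticParams(model_id="E", delta_N=delta_N,
                            delta_1=cap * rng.uniform(0.0, 0.95), k=k, **base)
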