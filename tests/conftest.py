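"""Shared fixtures.

The two session-scoped "study" fixtures run the expensive simulate-and-fit
pipelines once; several tests assert different properties of their output.
Problem sizes follow the package's smoke-scale defaults (see
docs/methods.md): five replications of the two-class high-separation
condition at N=2000, J=20, and three replications of the single-class
condition at N=1000, J=10.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mixtree.estimation import (
    FitConfig,
    eap_scores,
    fit_step1,
    posterior_class_probs,
)
from mixtree.model import count_parameters
from mixtree.selection import information_criteria
from mixtree.simulation import (
    SimulationDesign,
    evaluate_recovery,
    generate_dataset,
)

STUDY_SEED = 20260


def _rep_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclasses.dataclass
class TwoClassStudy:
    """Replication-level results of the two-class recovery study."""

    aic_picks: list[int]
    logliks: list[dict[int, float]]
    hit_rates: list[float]
    param_bias: pd.DataFrame  # replications x parameter families (C=2 fit)
    ers_bias_high: list[float]  # MixTree-1 eta bias, larger-ERS-loading class
    ers_bias_low: list[float]  # MixTree-1 eta bias, smaller-ERS-loading class
    theta_bias: list[float]  # MixTree-1 theta bias averaged over classes
    alpha_ers_order_ok: list[bool]  # canonical label order check


@pytest.fixture(scope="session")
def two_class_study() -> TwoClassStudy:
    """Fit MixTree-1..3 to five two-class high-separation replications."""
    reps = 5
    design = SimulationDesign(
        C_true=2, class_size_profile="equal", N=2000, J=20, separation="high"
    )
    aic_picks, logliks, hits = [], [], []
    biases, ers_hi, ers_lo, theta_b, order_ok = [], [], [], [], []
    for seed in _rep_seeds(STUDY_SEED, reps):
        data = generate_dataset(design, seed=seed)
        fits, aics = {}, {}
        for C in (1, 2, 3):
            cfg = FitConfig(quad_points=11, n_starts=2, seed=seed + C)
            fits[C] = fit_step1(data.responses, C, cfg)
            aics[C] = information_criteria(
                fits[C].loglik, C, design.J, design.N, fits[C].params.pi
            )[0]
        aic_picks.append(min(aics, key=aics.get))
        logliks.append({C: fits[C].loglik for C in fits})

        post2 = posterior_class_probs(fits[2], data.responses)
        rec2 = evaluate_recovery(data, fits[2], posterior=post2)
        hits.append(rec2.hit_rate)
        biases.append(rec2.params.set_index("family")["bias"])
        order_ok.append(
            bool(np.all(np.diff(fits[2].params.alpha_ers) <= 1e-12))
        )

        eap1 = eap_scores(fits[1], data.responses)
        rec1 = evaluate_recovery(data, fits[1], eap=eap1)
        scores = rec1.scores
        eta = scores[scores.family == "eta"].set_index("true_class")["bias"]
        theta = scores[scores.family == "theta"]["bias"]
        hi = int(np.argmax(data.true_params.alpha_ers)) + 1
        lo = int(np.argmin(data.true_params.alpha_ers)) + 1
        ers_hi.append(float(eta[hi]))
        ers_lo.append(float(eta[lo]))
        theta_b.append(float(theta.mean()))
    return TwoClassStudy(
        aic_picks=aic_picks,
        logliks=logliks,
        hit_rates=hits,
        param_bias=pd.concat(biases, axis=1).T.reset_index(drop=True),
        ers_bias_high=ers_hi,
        ers_bias_low=ers_lo,
        theta_bias=theta_b,
        alpha_ers_order_ok=order_ok,
    )


@pytest.fixture(scope="session")
def single_class_selection() -> pd.DataFrame:
    """Information criteria for MixTree-1..3 on single-class data."""
    reps = 3
    design = SimulationDesign(
        C_true=1, class_size_profile="balanced", N=1000, J=10,
        separation="medium",
    )
    rows = []
    for rep, seed in enumerate(_rep_seeds(STUDY_SEED + 1, reps)):
        data = generate_dataset(design, seed=seed)
        for C in (1, 2, 3):
            cfg = FitConfig(quad_points=7, n_starts=1 if C == 1 else 2,
                            seed=seed + C)
            fit = fit_step1(data.responses, C, cfg)
            aic, bic, hbic = information_criteria(
                fit.loglik, C, design.J, design.N, fit.params.pi
            )
            rows.append(
                {"rep": rep, "C": C, "loglik": fit.loglik, "aic": aic,
                 "bic": bic, "hbic": hbic}
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_two_class_data():
    """One small two-class dataset for cheap structural tests."""
    design = SimulationDesign(
        C_true=2, class_size_profile="equal", N=400, J=8, separation="high"
    )
    return generate_dataset(design, seed=STUDY_SEED + 2)
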