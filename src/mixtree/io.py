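"""Delimited-text readers and writers for MixTree inputs and results.

Responses travel as CSV with a header row of item labels, one respondent
per row, categories as integers 1-4, and empty cells for missing values.
All person/item/class indices in files are 1-based.
"""

from __future__ import annotations

import json
import logging
import pathlib

import numpy as np
import pandas as pd

from .estimation import (
    ClassificationError,
    CovariateModel,
    FitResult,
    LatentPosterior,
)
from .model import (
    MixTreeParameters,
    PseudoItemMatrix,
    ResponseMatrix,
    decompose_to_pseudo_items,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_responses",
    "write_responses",
    "read_covariates",
    "write_pseudo_items",
    "parameters_to_frame",
    "parameters_from_frame",
    "write_fit",
    "read_fit",
    "write_posterior",
]


def read_responses(path) -> ResponseMatrix:
    """Read a response CSV, validating categories and logging frequencies."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no respondent rows found")
    values = df.to_numpy(dtype=float)
    try:
        responses = ResponseMatrix(values, item_names=list(df.columns))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    for j, name in enumerate(responses.item_names):
        col = values[:, j]
        counts = {c: int(np.sum(col == c)) for c in (1, 2, 3, 4)}
        logger.debug("item %s category frequencies: %s", name, counts)
    return responses


def write_responses(responses: ResponseMatrix, path) -> None:
    df = pd.DataFrame(responses.values, columns=responses.item_names)
    df.to_csv(path, index=False, float_format="%.0f")


def read_covariates(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no covariate rows found")
    return df.to_numpy(dtype=float), list(df.columns)


def write_pseudo_items(
    pseudo: PseudoItemMatrix, path, item_names: list[str] | None = None
) -> None:
    """Export the 3J pseudo-item columns; structural missing cells are blank."""
    J = pseudo.n_items
    if item_names is None:
        item_names = [f"item{j + 1}" for j in range(J)]
    cols = {}
    for j in range(J):
        cols[f"{item_names[j]}_node1"] = pseudo.y1[:, j]
        cols[f"{item_names[j]}_node2"] = pseudo.y2[:, j]
        cols[f"{item_names[j]}_node3"] = pseudo.y3[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.0f")


def parameters_to_frame(params: MixTreeParameters) -> pd.DataFrame:
    """Long-format parameter table (class 0 rows = class-invariant)."""
    rows = []
    for j in range(params.n_items):
        rows.append({"parameter": "alpha_trait", "item": j + 1, "class": 0,
                     "value": params.alpha_trait[j]})
        rows.append({"parameter": "beta1", "item": j + 1, "class": 0,
                     "value": params.beta1[j]})
        for c in range(params.n_classes):
            rows.append({"parameter": "omega", "item": j + 1, "class": c + 1,
                         "value": params.omega[j, c]})
            rows.append({"parameter": "beta2", "item": j + 1, "class": c + 1,
                         "value": params.beta2[j, c]})
            rows.append({"parameter": "beta3", "item": j + 1, "class": c + 1,
                         "value": params.beta3[j, c]})
    for c in range(params.n_classes):
        rows.append({"parameter": "alpha_ers", "item": 0, "class": c + 1,
                     "value": params.alpha_ers[c]})
        rows.append({"parameter": "pi", "item": 0, "class": c + 1,
                     "value": params.pi[c]})
    rows.append({"parameter": "latent_corr", "item": 0, "class": 0,
                 "value": params.latent_corr})
    return pd.DataFrame(rows)


def parameters_from_frame(df: pd.DataFrame) -> MixTreeParameters:
    def grab(name):
        return df[df.parameter == name].sort_values(["item", "class"])

    J = int(df[df.parameter == "alpha_trait"]["item"].max())
    C = int(df[df.parameter == "omega"]["class"].max())

    def grid(name):
        sub = df[df.parameter == name]
        out = np.empty((J, C))
        for _, r in sub.iterrows():
            out[int(r["item"]) - 1, int(r["class"]) - 1] = r["value"]
        return out

    alpha = grab("alpha_trait")["value"].to_numpy()
    beta1 = grab("beta1")["value"].to_numpy()
    aers = grab("alpha_ers")["value"].to_numpy()
    pi = grab("pi")["value"].to_numpy()
    corr = float(df[df.parameter == "latent_corr"]["value"].iloc[0])
    return MixTreeParameters(
        alpha_trait=alpha, beta1=beta1, omega=grid("omega"), alpha_ers=aers,
        beta2=grid("beta2"), beta3=grid("beta3"), pi=pi, latent_corr=corr,
    )


def write_fit(fit: FitResult, out_dir) -> pathlib.Path:
    """Persist a Step-1 fit: parameter table plus a structured run log."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parameters_to_frame(fit.params).to_csv(out / "parameters.csv", index=False)
    meta = {
        "loglik": fit.loglik,
        "n_classes": fit.n_classes,
        "n_items": fit.params.n_items,
        "n_persons": fit.n_persons,
        "n_starts": fit.n_starts,
        "start_logliks": fit.start_logliks,
        "converged": fit.converged,
        "monotone_violation": fit.monotone_violation,
        "label_permutation": (
            fit.label_permutation.tolist()
            if fit.label_permutation is not None else None
        ),
        "config": {
            "quad_points": fit.config.quad_points,
            "n_starts": fit.config.n_starts,
            "tolerance": fit.config.tolerance,
            "max_iter": fit.config.max_iter,
            "seed": fit.config.seed,
            "estimate_latent_corr": fit.config.estimate_latent_corr,
            "latent_corr": fit.config.latent_corr,
            "omega_nonnegative": fit.config.omega_nonnegative,
        },
    }
    (out / "run.json").write_text(json.dumps(meta, indent=2))
    return out


def read_fit(fit_dir) -> tuple[MixTreeParameters, dict]:
    fit_dir = pathlib.Path(fit_dir)
    params = parameters_from_frame(pd.read_csv(fit_dir / "parameters.csv"))
    meta = json.loads((fit_dir / "run.json").read_text())
    return params, meta


def write_posterior(
    posterior: LatentPosterior, error: ClassificationError | None, out_dir
) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    C = posterior.class_post.shape[1]
    post = pd.DataFrame(
        posterior.class_post, columns=[f"class{c + 1}" for c in range(C)]
    )
    post.insert(0, "person", np.arange(len(post)) + 1)
    post["assignment"] = posterior.assignment + 1
    post["theta_eap"] = posterior.eap.theta
    post["eta_eap"] = posterior.eap.eta
    post["theta_se"] = posterior.eap.se_theta
    post["eta_se"] = posterior.eap.se_eta
    post.to_csv(out / "posterior.csv", index=False)
    if error is not None:
        pd.DataFrame(
            error.D,
            index=[f"true{c + 1}" for c in range(C)],
            columns=[f"assigned{c + 1}" for c in range(C)],
        ).to_csv(out / "classification_error.csv")


def write_covariate_model(model: CovariateModel, names: list[str], out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in range(model.n_classes):
        rows.append({"class": c + 1, "term": "intercept",
                     "estimate": model.gamma0[c], "se": model.se_gamma0[c]})
        for t, name in enumerate(names):
            rows.append({"class": c + 1, "term": name,
                         "estimate": model.gamma[t, c], "se": model.se_gamma[t, c]})
    pd.DataFrame(rows).to_csv(out / "covariate_effects.csv", index=False)
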