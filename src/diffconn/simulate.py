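"""Synthetic two-condition expression data with planted structure.

The generator emulates the statistical shape of a two-condition log2
microarray matrix: per-feature baselines, mean shifts for planted
differentially expressed (DE) features, latent-factor co-expression
modules, and "rewired hub" features whose module loading is knocked out in
one condition — the pattern that produces a large degree drop between the
two condition-specific correlation networks.

Generative model, per feature g and sample s::

    x_gs = mu_g + beta_g * I[s in condition B] + lambda_g(c(s)) * f_{m(g),s} + eps_gs

with mu_g ~ Normal(8, 1.5) (log2 scale), beta_g = 0 except for planted DE
features where beta_g = +/- Normal(de_log2fc_mean, de_log2fc_sd), module
factors f ~ Normal(0, 1) per (module, sample), loading lambda_g(c) equal to
``loading`` where the feature is wired and 0 where a rewired hub is
unwired, and eps ~ Normal(0, noise_sd).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CODING, NON_CODING, ExpressionMatrix, _header_comment

COND_A = "EC"
COND_B = "TC-EC"

#: rewiring directions: "loss" = loading knocked out in condition B,
#: "gain" = loading absent in condition A, present in B.
LOSS = "loss"
GAIN = "gain"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-condition experiment.

    Defaults describe the desk-scale study the recovery tests run on:
    2,000 features of which 10% are non-coding, 20 samples per condition,
    5% DE features with |log2FC| centered at 2, 10 latent modules of 25
    members at unit loading and unit noise, and 10 rewired hubs that lose
    their module loading in condition B.
    """

    n_coding: int = 1800
    n_noncoding: int = 200
    n_samples_per_condition: int = 20
    de_fraction: float = 0.05
    de_log2fc_mean: float = 2.0
    de_log2fc_sd: float = 0.5
    n_modules: int = 10
    module_size: int = 25
    loading: float = 1.0
    n_rewired_hubs: int = 10
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_coding",
            "n_noncoding",
            "n_samples_per_condition",
            "n_modules",
            "module_size",
            "n_rewired_hubs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.de_log2fc_sd < 0:
            raise ValueError("de_log2fc_sd must be >= 0")
        if self.n_rewired_hubs > self.n_modules * self.module_size:
            raise ValueError("n_rewired_hubs exceeds total module membership")
        if self.n_modules * self.module_size > self.n_coding + self.n_noncoding:
            raise ValueError("module membership exceeds feature count")

    def to_dict(self) -> dict[str, object]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment.

    ``rewired_hubs`` maps each hub feature id to its rewiring direction
    ("loss": wired in A only; "gain": wired in B only); ``module_of`` maps
    module members to their module index.
    """

    de_up: set[str]
    de_down: set[str]
    rewired_hubs: dict[str, str]
    module_of: dict[str, int]
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.de_up & self.de_down:
            raise ValueError("a feature cannot be both up- and down-regulated")
        outside = set(self.rewired_hubs) - set(self.module_of)
        if outside:
            raise ValueError(f"rewired hub {outside.pop()!r} is not a module member")


def simulate_two_condition_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one synthetic two-condition experiment.

    A single :class:`numpy.random.Generator` keyed by ``config.seed``
    drives every draw, so identical configs give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_features = config.n_coding + config.n_noncoding
    n = config.n_samples_per_condition
    n_samples = 2 * n
    if n < 2:
        raise ValueError("n_samples_per_condition must be >= 2")

    feature_ids = np.array(
        [f"gene{i + 1:05d}" for i in range(config.n_coding)]
        + [f"n{i + 1:06d}" for i in range(config.n_noncoding)]
    )
    feature_type = np.array(
        [CODING] * config.n_coding + [NON_CODING] * config.n_noncoding
    )
    sample_ids = [f"{COND_A}_{i + 1}" for i in range(n)] + [
        f"{COND_B}_{i + 1}" for i in range(n)
    ]
    in_b = np.zeros(n_samples, dtype=bool)
    in_b[n:] = True

    # planted structure -------------------------------------------------
    n_de = int(round(config.de_fraction * n_features))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    beta = np.zeros(n_features)
    signs = rng.choice([1.0, -1.0], size=n_de)
    beta[de_idx] = signs * rng.normal(
        config.de_log2fc_mean, config.de_log2fc_sd, size=n_de
    )

    n_members = config.n_modules * config.module_size
    non_de = np.setdiff1d(np.arange(n_features), de_idx, assume_unique=False)
    # module members drawn from non-DE features when possible so the DE and
    # rewiring signals stay separable in recovery tests
    pool = non_de if len(non_de) >= n_members else np.arange(n_features)
    member_idx = rng.choice(pool, size=n_members, replace=False)
    module_of_idx = np.full(n_features, -1)
    for m in range(config.n_modules):
        module_of_idx[member_idx[m * config.module_size : (m + 1) * config.module_size]] = m

    # hubs spread round-robin over modules; all default to "loss" in B,
    # reproducing the large EC -> TC-EC degree drops the statistic targets
    hub_idx: list[int] = []
    if config.n_rewired_hubs:
        per_module = [
            member_idx[m * config.module_size : (m + 1) * config.module_size]
            for m in range(config.n_modules)
        ]
        m = 0
        taken = {mm: 0 for mm in range(config.n_modules)}
        while len(hub_idx) < config.n_rewired_hubs:
            if taken[m] < config.module_size:
                hub_idx.append(int(per_module[m][taken[m]]))
                taken[m] += 1
            m = (m + 1) % config.n_modules

    # assemble ----------------------------------------------------------
    mu = rng.normal(8.0, 1.5, size=n_features)
    factors = rng.normal(0.0, 1.0, size=(max(config.n_modules, 1), n_samples))
    eps = rng.normal(0.0, config.noise_sd, size=(n_features, n_samples))

    x = mu[:, None] + beta[:, None] * in_b[None, :] + eps
    if config.n_modules:
        lam = np.zeros((n_features, n_samples))
        members = module_of_idx >= 0
        lam[members, :] = config.loading
        for g in hub_idx:
            lam[g, in_b] = 0.0  # loss of loading in condition B
        x = x + lam * factors[np.clip(module_of_idx, 0, None), :]

    values = pd.DataFrame(x, index=feature_ids, columns=sample_ids)
    condition_of = pd.Series(
        np.where(in_b, COND_B, COND_A), index=sample_ids
    )
    feature_type_of = pd.Series(feature_type, index=feature_ids)
    em = ExpressionMatrix(values, condition_of, feature_type_of)

    truth = SyntheticTruth(
        de_up={feature_ids[i] for i in de_idx if beta[i] > 0},
        de_down={feature_ids[i] for i in de_idx if beta[i] < 0},
        rewired_hubs={feature_ids[i]: LOSS for i in hub_idx},
        module_of={
            feature_ids[i]: int(module_of_idx[i])
            for i in range(n_features)
            if module_of_idx[i] >= 0
        },
        config=config,
    )
    return em, truth


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """One row per planted feature with its roles (DE direction, hub
    rewiring direction, module index)."""
    planted = sorted(
        truth.de_up | truth.de_down | set(truth.rewired_hubs) | set(truth.module_of)
    )
    rows = []
    for f in planted:
        rows.append(
            {
                "feature_id": f,
                "de": "up" if f in truth.de_up else ("down" if f in truth.de_down else "none"),
                "rewired": truth.rewired_hubs.get(f, "none"),
                "module": truth.module_of.get(f, -1),
            }
        )
    return pd.DataFrame(rows, columns=["feature_id", "de", "rewired", "module"])


def write_truth_report(truth: SyntheticTruth, path: str | Path) -> None:
    df = truth_report(truth)
    with open(path, "w") as fh:
        fh.write(_header_comment("truth-report"))
        df.to_csv(fh, sep="\t", index=False)


def parse_truth_report(df: pd.DataFrame) -> SyntheticTruth:
    """Reconstruct the truth sets from a :func:`truth_report` table."""
    de_up = set(df.loc[df["de"] == "up", "feature_id"])
    de_down = set(df.loc[df["de"] == "down", "feature_id"])
    hubs = {
        r.feature_id: r.rewired
        for r in df.itertuples()
        if r.rewired != "none"
    }
    module_of = {
        r.feature_id: int(r.module) for r in df.itertuples() if int(r.module) >= 0
    }
    return SyntheticTruth(de_up, de_down, hubs, module_of)


def read_truth_report(path: str | Path) -> SyntheticTruth:
    return parse_truth_report(pd.read_csv(path, sep="\t", comment="#"))
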