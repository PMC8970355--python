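"""Multilocus Hudson-Kreitman-Aguade neutrality test with per-locus
("partial HKA") contributions.

The classical 1987 method-of-moments fit is used with the population-size
ratio f fixed at 1: for each locus i,

    S_i + D_i = theta_i * (L_pol_i * a(n_i) + L_div_i * (T + 1)),

with a(n) the harmonic number sum_{j<n} 1/j, S_i the segregating-site count
within the focal species and D_i the between-species divergence in
difference-count units.  T-hat solves

    sum_i D_i = sum_i theta_i(T) * L_div_i * (T + 1)

by bisection on the monotone residual; theta_i then follows per locus.
The divergence observation is, by default, the difference count between one
deterministic cross-species strain pair (the first strain of each species),
exactly the quantity whose variance the classical model describes.  A
variance-reduced alternative (the mean over all cross pairs) is available
via ``divergence="mean"``; note that averaging shrinks the sampling
variance of D below the model's Var[D], which makes the chi-square test
noticeably conservative.

Expectations and variances follow the classical model:

    E[S_i]   = theta_i L_pol_i a(n_i)
    Var[S_i] = E[S_i] + (theta_i L_pol_i)^2 b(n_i),  b(n) = sum_{j<n} 1/j^2
    E[D_i]   = theta_i L_div_i (T + 1)
    Var[D_i] = E[D_i] + (theta_i L_div_i)^2

partial_i = (S_i - E[S_i])^2 / Var[S_i] + (D_i - E[D_i])^2 / Var[D_i],
X^2 = sum_i partial_i, df = L - 1, p from the upper chi-square tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import chi2

from .errors import ValidationError
from .io import GenePanel
from .popgen import (
    encode_alignment,
    mean_pairwise_differences,
    segregating_sites,
)

import numpy as np


def harmonic_a(n: int) -> float:
    return sum(1.0 / j for j in range(1, n))


def harmonic_b(n: int) -> float:
    return sum(1.0 / j**2 for j in range(1, n))


@dataclass
class HKALocusInput:
    """One row of an HKAdirect-style input table (factor_chrm fixed to 1,
    i.e. autosomal nuclear genes)."""

    locus_id: str
    nsam: int
    S: float
    D: float
    L_pol: int
    L_div: int

    def __post_init__(self) -> None:
        if self.nsam < 2:
            raise ValidationError(f"{self.locus_id}: nsam must be >= 2")
        if self.S < 0 or self.D < 0:
            raise ValidationError(f"{self.locus_id}: S and D must be >= 0")
        if self.L_pol <= 0 or self.L_div <= 0:
            raise ValidationError(f"{self.locus_id}: lengths must be > 0")


@dataclass
class HKAModel:
    theta: dict[str, float]  # per-site theta-hat per locus
    T_hat: float
    f: float = 1.0
    X2: float | None = None
    df: int | None = None
    p_value: float | None = None
    partials: dict[str, float] = field(default_factory=dict)
    expected_S: dict[str, float] = field(default_factory=dict)
    expected_D: dict[str, float] = field(default_factory=dict)


def build_hka_input(
    panel: GenePanel,
    focal_species: str,
    other_species: str,
    divergence: str = "pair",
) -> list[HKALocusInput]:
    """Per-gene (nsam, S, D, L) rows for the focal species.

    S is counted on complete-deletion columns over all used strains (focal
    plus other species); D is the cross-species difference count on the same
    column set, so polymorphism and divergence are surveyed over identical
    sites (L_pol = L_div).  ``divergence="pair"`` (default) observes one
    deterministic cross pair, matching the classical variance model;
    ``"mean"`` averages over all cross pairs.
    """
    if divergence not in ("pair", "mean"):
        raise ValidationError(f"unknown divergence observation {divergence!r}")
    rows = []
    for gid, aln in panel.genes.items():
        focal = aln.strains_of(focal_species)
        other = aln.strains_of(other_species)
        if len(focal) < 2:
            warnings.warn(
                f"gene {gid}: fewer than 2 {focal_species} strains; excluded"
            )
            continue
        if not other:
            warnings.warn(f"gene {gid}: no {other_species} strains; excluded")
            continue
        used = focal + other
        mat = encode_alignment(aln, used)
        keep = (mat >= 0).all(axis=0)
        L = int(keep.sum())
        if L == 0:
            warnings.warn(f"gene {gid}: no complete columns; excluded")
            continue
        sub = mat[:, keep]
        nf = len(focal)
        S = int((sub[:nf] != sub[0]).any(axis=0).sum())
        if divergence == "pair":
            D = float((sub[0] != sub[nf]).sum())
        else:
            diffs = []
            for i in range(nf):
                for j in range(nf, len(used)):
                    diffs.append(int((sub[i] != sub[j]).sum()))
            D = float(np.mean(diffs))
        rows.append(
            HKALocusInput(locus_id=gid, nsam=nf, S=S, D=D, L_pol=L, L_div=L)
        )
    return rows


def _residual(T: float, inputs: list[HKALocusInput]) -> float:
    """g(T) = observed total divergence minus the model's prediction at T;
    strictly decreasing in T."""
    pred = 0.0
    for row in inputs:
        theta_site = (row.S + row.D) / (
            row.L_pol * harmonic_a(row.nsam) + row.L_div * (T + 1.0)
        )
        pred += theta_site * row.L_div * (T + 1.0)
    return sum(r.D for r in inputs) - pred


def fit_hka(
    inputs: list[HKALocusInput], tol: float = 1e-10, max_steps: int = 200
) -> HKAModel:
    """Method-of-moments parameter fit (f = 1)."""
    if len(inputs) < 2:
        raise ValidationError("HKA requires at least 2 loci")
    if all(r.S + r.D == 0 for r in inputs):
        raise ValidationError("all loci have S + D = 0: no data")
    if _residual(0.0, inputs) <= 0:
        T_hat = 0.0
    else:
        lo, hi = 0.0, 1.0
        while _residual(hi, inputs) > 0:
            hi *= 2.0
            if hi > 1e12:
                raise ValidationError("HKA divergence-time fit did not bracket")
        for _ in range(max_steps):
            mid = (lo + hi) / 2.0
            if _residual(mid, inputs) > 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        else:
            raise ValidationError(
                f"HKA bisection did not converge within {max_steps} steps"
            )
        T_hat = (lo + hi) / 2.0
    theta = {}
    for row in inputs:
        denom = row.L_pol * harmonic_a(row.nsam) + row.L_div * (T_hat + 1.0)
        theta[row.locus_id] = (row.S + row.D) / denom
    return HKAModel(theta=theta, T_hat=T_hat)


def hka_statistic(inputs: list[HKALocusInput], model: HKAModel) -> HKAModel:
    """Complete the model with expectations, per-locus partials, X^2, df, p."""
    X2 = 0.0
    for row in inputs:
        th = model.theta[row.locus_id]
        eS = th * row.L_pol * harmonic_a(row.nsam)
        eD = th * row.L_div * (model.T_hat + 1.0)
        model.expected_S[row.locus_id] = eS
        model.expected_D[row.locus_id] = eD
        varS = eS + (th * row.L_pol) ** 2 * harmonic_b(row.nsam)
        varD = eD + (th * row.L_div) ** 2
        if varS <= 0 or varD <= 0:
            warnings.warn(
                f"locus {row.locus_id}: zero variance (theta-hat = 0); "
                "contributes 0"
            )
            model.partials[row.locus_id] = 0.0
            continue
        part = (row.S - eS) ** 2 / varS + (row.D - eD) ** 2 / varD
        model.partials[row.locus_id] = part
        X2 += part
    model.X2 = X2
    model.df = len(inputs) - 1
    model.p_value = float(chi2.sf(X2, model.df)) if model.df > 0 else None
    return model


def hka_test(inputs: list[HKALocusInput]) -> HKAModel:
    return hka_statistic(inputs, fit_hka(inputs))


def hka_table(
    panel: GenePanel, focal_species: str, other_species: str
) -> tuple[pd.DataFrame, HKAModel]:
    """Convenience: build inputs from a panel, fit, and tabulate."""
    inputs = build_hka_input(panel, focal_species, other_species)
    model = hka_test(inputs)
    df = pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in inputs],
            "nsam": [r.nsam for r in inputs],
            "S": [r.S for r in inputs],
            "D": [r.D for r in inputs],
            "L": [r.L_pol for r in inputs],
            "theta_site": [model.theta[r.locus_id] for r in inputs],
            "E_S": [model.expected_S[r.locus_id] for r in inputs],
            "E_D": [model.expected_D[r.locus_id] for r in inputs],
            "partial_hka": [model.partials[r.locus_id] for r in inputs],
        }
    )
    return df, model
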