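"""Per-gene population-genetic and molecular-evolution statistics.

Within-species nucleotide diversity (pi), segregating sites (S), Tajima's D,
between-species absolute divergence (dxy), Hudson's Fst, and Nei-Gojobori
(1986) pairwise dS/dN with Jukes-Cantor correction.

Missing-data policy (documented design choice): segregating sites and the
mean pairwise difference count feeding Tajima's D use *complete deletion* --
any column containing a gap or ambiguity (N/X) in any selected strain is
dropped before counting, so numerator and denominator of D see the same
column set.  pi and dxy use *pairwise deletion*: each strain pair is compared
over the columns where both members are unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import ValidationError
from .io import GenePanel, SpeciesAlignment

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
_STOPS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)


def encode_alignment(aln: SpeciesAlignment, strains: Sequence[str]) -> np.ndarray:
    """Integer-encode selected rows: A/C/G/T -> 0..3, everything else -> -1."""
    mat = np.full((len(strains), aln.length), -1, dtype=np.int8)
    for i, s in enumerate(strains):
        row = aln.seqs[s]
        for j, ch in enumerate(row):
            mat[i, j] = _CODE.get(ch, -1)
    return mat


def _complete_columns(mat: np.ndarray) -> np.ndarray:
    return mat[:, (mat >= 0).all(axis=0)]


# ---------------------------------------------------------------------------
# S, pi, dxy, Fst


def segregating_sites(aln: SpeciesAlignment, strains: Sequence[str]) -> int:
    """Number of polymorphic columns among *strains* under complete deletion."""
    if len(strains) < 2:
        raise ValidationError("segregating_sites requires >= 2 strains")
    sub = _complete_columns(encode_alignment(aln, strains))
    if sub.shape[1] == 0:
        return 0
    return int((sub != sub[0]).any(axis=0).sum())


def complete_deletion_length(aln: SpeciesAlignment, strains: Sequence[str]) -> int:
    """Number of columns surviving complete deletion for *strains*."""
    mat = encode_alignment(aln, strains)
    return int((mat >= 0).all(axis=0).sum())


def mean_pairwise_differences(
    aln: SpeciesAlignment, strains: Sequence[str]
) -> float:
    """Mean pairwise difference *count* on the complete-deletion column set.

    This is the k-hat that enters Tajima's D, computed on the same columns
    as :func:`segregating_sites`.
    """
    if len(strains) < 2:
        raise ValidationError("mean_pairwise_differences requires >= 2 strains")
    sub = _complete_columns(encode_alignment(aln, strains))
    n = len(strains)
    total = 0
    for i, j in combinations(range(n), 2):
        total += int((sub[i] != sub[j]).sum())
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(aln: SpeciesAlignment, strains: Sequence[str]) -> float | None:
    """Per-site pi: mean over strain pairs of differences / compared sites
    (pairwise deletion).  Pairs with zero comparable sites are excluded with
    a warning; returns None if every pair is excluded."""
    if len(strains) < 2:
        raise ValidationError("nucleotide_diversity requires >= 2 strains")
    mat = encode_alignment(aln, strains)
    vals = []
    for i, j in combinations(range(len(strains)), 2):
        ok = (mat[i] >= 0) & (mat[j] >= 0)
        ncomp = int(ok.sum())
        if ncomp == 0:
            warnings.warn(
                f"gene {aln.gene_id}: pair ({strains[i]}, {strains[j]}) has no "
                "comparable sites; excluded from pi"
            )
            continue
        vals.append(int((mat[i][ok] != mat[j][ok]).sum()) / ncomp)
    if not vals:
        return None
    return float(np.mean(vals))


def dxy(
    aln: SpeciesAlignment,
    strains_a: Sequence[str],
    strains_b: Sequence[str],
) -> float | None:
    """Per-site absolute divergence: mean over cross-species pairs of
    differences / compared sites (pairwise deletion)."""
    if not strains_a or not strains_b:
        raise ValidationError("dxy requires non-empty strain sets for both species")
    mat_a = encode_alignment(aln, strains_a)
    mat_b = encode_alignment(aln, strains_b)
    vals = []
    for i in range(len(strains_a)):
        for j in range(len(strains_b)):
            ok = (mat_a[i] >= 0) & (mat_b[j] >= 0)
            ncomp = int(ok.sum())
            if ncomp == 0:
                warnings.warn(
                    f"gene {aln.gene_id}: cross pair ({strains_a[i]}, "
                    f"{strains_b[j]}) has no comparable sites; excluded from dxy"
                )
                continue
            vals.append(int((mat_a[i][ok] != mat_b[j][ok]).sum()) / ncomp)
    if not vals:
        return None
    return float(np.mean(vals))


def hudson_fst(pi_a: float, pi_b: float, d_xy: float) -> float | None:
    """Hudson's Fst = 1 - mean within-species pi / dxy (None when dxy = 0).

    Negative values are reported as computed, never clamped.
    """
    if pi_a < 0 or pi_b < 0 or d_xy < 0:
        raise ValidationError("hudson_fst inputs must be non-negative")
    if d_xy == 0:
        return None
    return 1.0 - ((pi_a + pi_b) / 2.0) / d_xy


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass
class TajimaConstants:
    """The a1..e2 coefficients of Tajima (1989) for sample size n."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("Tajima constants require n >= 2")
        n = self.n
        self.a1 = sum(1.0 / i for i in range(1, n))
        self.a2 = sum(1.0 / i**2 for i in range(1, n))
        self.b1 = (n + 1) / (3.0 * (n - 1))
        self.b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        self.c1 = self.b1 - 1.0 / self.a1
        self.c2 = self.b2 - (n + 2) / (self.a1 * n) + self.a2 / self.a1**2
        self.e1 = self.c1 / self.a1
        self.e2 = self.c2 / (self.a1**2 + self.a2)


def tajimas_d(S: int, k_hat: float, n: int) -> float | None:
    """Tajima's D from segregating sites S and mean pairwise difference
    count k-hat (count units, not per site).  Returns None when S = 0."""
    if S < 0:
        raise ValidationError("S must be >= 0")
    if n < 4:
        warnings.warn(f"Tajima's D with n={n} < 4: variance terms are unstable")
    if S == 0:
        return None
    c = TajimaConstants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return None
    return (k_hat - S / c.a1) / np.sqrt(var)


def tajimas_d_from_alignment(
    aln: SpeciesAlignment, strains: Sequence[str]
) -> float | None:
    S = segregating_sites(aln, strains)
    if S == 0:
        return None
    k_hat = mean_pairwise_differences(aln, strains)
    return tajimas_d(S, k_hat, len(strains))


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) pairwise dS/dN


@dataclass
class NG86Pair:
    """Pairwise NG86 counts: pair-averaged synonymous / nonsynonymous sites,
    pathway-averaged difference counts, proportions and JC-corrected rates."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    pS: float | None
    pN: float | None
    dS: float | None
    dN: float | None
    codons_compared: int


def _syn_fraction(codon: str) -> float:
    """Per-codon synonymous site count: sum over the three positions of the
    fraction (out of 3) of single-base neighbours that are synonymous.
    Changes to stop codons count as nonsynonymous (the site total per codon
    is always exactly 3)."""
    aa = _AA[codon]
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in _STOPS and _AA[alt] == aa:
                syn += 1.0 / 3.0
    return syn


_SYN_CACHE: dict[str, float] = {}
_PATH_CACHE: dict[tuple[str, str], tuple[float, float] | None] = {}


def _codon_sites(codon: str) -> float:
    if codon not in _SYN_CACHE:
        _SYN_CACHE[codon] = _syn_fraction(codon)
    return _SYN_CACHE[codon]


def _codon_pair_diffs(c1: str, c2: str) -> tuple[float, float] | None:
    """Pathway-averaged (syn, nonsyn) difference counts between two codons.

    All orderings of the single-base steps are enumerated; paths passing
    through a stop codon are excluded and the weights renormalised over the
    survivors.  Returns None when every path is blocked.
    """
    key = (c1, c2)
    if key in _PATH_CACHE:
        return _PATH_CACHE[key]
    pos = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in permutations(pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for p in order:
            nxt = cur[: p] + c2[p] + cur[p + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            results.append((sd, nd))
    out: tuple[float, float] | None
    if not results:
        out = None
    else:
        out = (
            float(np.mean([r[0] for r in results])),
            float(np.mean([r[1] for r in results])),
        )
    _PATH_CACHE[key] = out
    return out


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(seq1: str, seq2: str) -> NG86Pair:
    """Nei-Gojobori (1986) dS/dN between two in-frame coding sequences.

    Codons containing a gap or N in either sequence are skipped pairwise.
    Internal stop codons raise; codon pairs whose every mutational pathway
    crosses a stop are skipped with a warning.
    """
    if len(seq1) != len(seq2):
        raise ValidationError("ng86_pairwise requires equal-length sequences")
    if len(seq1) % 3 != 0:
        raise ValidationError(
            f"sequence length {len(seq1)} is not a multiple of 3"
        )
    s_sites1 = s_sites2 = 0.0
    sd = nd = 0.0
    ncodons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        for which, c in (("first", c1), ("second", c2)):
            if c in _STOPS:
                raise ValidationError(
                    f"stop codon {c} in {which} sequence at nucleotide "
                    f"position {i + 1}"
                )
        if c1 == c2:
            pair = (0.0, 0.0)
        else:
            pair = _codon_pair_diffs(c1, c2)
            if pair is None:
                warnings.warn(
                    f"codon pair {c1}/{c2} at position {i + 1}: all mutational "
                    "paths pass through stop codons; codon skipped"
                )
                continue
        s_sites1 += _codon_sites(c1)
        s_sites2 += _codon_sites(c2)
        sd += pair[0]
        nd += pair[1]
        ncodons += 1
    syn_sites = (s_sites1 + s_sites2) / 2.0
    nonsyn_sites = 3.0 * ncodons - syn_sites
    pS = sd / syn_sites if syn_sites > 0 else None
    pN = nd / nonsyn_sites if nonsyn_sites > 0 else None
    return NG86Pair(
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        pS=pS,
        pN=pN,
        dS=_jc_correct(pS) if pS is not None else None,
        dN=_jc_correct(pN) if pN is not None else None,
        codons_compared=ncodons,
    )


def _median_or_none(values: Iterable[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# Per-gene summary table


@dataclass
class PopGenRecord:
    """One row of the genome-wide statistics table (one gene)."""

    gene_id: str
    category: str
    n_a: int
    n_b: int
    S_a: int | None
    S_b: int | None
    pi_a: float | None
    pi_b: float | None
    tajima_a: float | None
    tajima_b: float | None
    dxy: float | None
    fst: float | None
    pi_over_dxy_a: float | None
    pi_over_dxy_b: float | None
    ds_within_a: float | None = None
    ds_within_b: float | None = None
    ds_between: float | None = None
    dn_within_a: float | None = None
    dn_within_b: float | None = None
    dn_between: float | None = None
    ds_ratio_within_between: float | None = None


def gene_record(
    aln: SpeciesAlignment,
    species_a: str,
    species_b: str,
    category: str = "background",
    codon_stats: bool = False,
) -> PopGenRecord:
    """All per-gene statistics for one alignment and one species pair."""
    sa = aln.strains_of(species_a)
    sb = aln.strains_of(species_b)
    have_a, have_b = len(sa) >= 2, len(sb) >= 2

    S_a = segregating_sites(aln, sa) if have_a else None
    S_b = segregating_sites(aln, sb) if have_b else None
    pi_a = nucleotide_diversity(aln, sa) if have_a else None
    pi_b = nucleotide_diversity(aln, sb) if have_b else None
    taj_a = tajimas_d_from_alignment(aln, sa) if have_a else None
    taj_b = tajimas_d_from_alignment(aln, sb) if have_b else None
    d = dxy(aln, sa, sb) if (sa and sb) else None
    fst = (
        hudson_fst(pi_a, pi_b, d)
        if (pi_a is not None and pi_b is not None and d is not None)
        else None
    )
    rec = PopGenRecord(
        gene_id=aln.gene_id,
        category=category,
        n_a=len(sa),
        n_b=len(sb),
        S_a=S_a,
        S_b=S_b,
        pi_a=pi_a,
        pi_b=pi_b,
        tajima_a=taj_a,
        tajima_b=taj_b,
        dxy=d,
        fst=fst,
        pi_over_dxy_a=(pi_a / d) if (pi_a is not None and d) else None,
        pi_over_dxy_b=(pi_b / d) if (pi_b is not None and d) else None,
    )
    if codon_stats and aln.length % 3 == 0:
        within_a = [
            ng86_pairwise(aln.seqs[x], aln.seqs[y]) for x, y in combinations(sa, 2)
        ]
        within_b = [
            ng86_pairwise(aln.seqs[x], aln.seqs[y]) for x, y in combinations(sb, 2)
        ]
        between = [
            ng86_pairwise(aln.seqs[x], aln.seqs[y]) for x in sa for y in sb
        ]
        rec.ds_within_a = _median_or_none(p.dS for p in within_a)
        rec.ds_within_b = _median_or_none(p.dS for p in within_b)
        rec.ds_between = _median_or_none(p.dS for p in between)
        rec.dn_within_a = _median_or_none(p.dN for p in within_a)
        rec.dn_within_b = _median_or_none(p.dN for p in within_b)
        rec.dn_between = _median_or_none(p.dN for p in between)
        pooled_within = _median_or_none(p.dS for p in within_a + within_b)
        if pooled_within is not None and rec.ds_between not in (None, 0.0):
            rec.ds_ratio_within_between = pooled_within / rec.ds_between
    return rec


def gene_summary(
    panel: GenePanel,
    species_a: str,
    species_b: str,
    codon_stats: bool = False,
) -> pd.DataFrame:
    """One :class:`PopGenRecord` row per gene of the panel."""
    rows = []
    for gid, aln in panel.genes.items():
        rec = gene_record(
            aln,
            species_a,
            species_b,
            category=panel.category_of[gid],
            codon_stats=codon_stats,
        )
        rows.append(vars(rec))
    return pd.DataFrame(rows)
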