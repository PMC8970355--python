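"""Synthetic-data generator with known ground truth.

Two locus classes are produced, matching the qualitative structure the
downstream statistics are designed to separate:

* **neutral loci** -- a two-population Kingman coalescent: independent
  coalescence within each species until the split time ``T_split`` (in units
  of 2N generations, pair-coalescence rate 1), then a single ancestral
  population.  Mutations are Poisson(theta/2 x branch length) on branches,
  each hitting a uniform site and substituting a uniform different base.
  Expected signatures: reciprocal monophyly, dxy > pi, positive Fst.

* **balanced loci** -- k deep allelic lineages predating the split, shared
  by both species (trans-species polymorphism).  k founder sequences are
  derived from a common ancestor by Binomial(L, d_bal) substitutions each;
  every strain of both species draws a lineage uniformly at random and
  within-lineage variation is added by a neutral coalescent with
  ``theta_within`` ignoring species labels.  Expected signatures:
  pi ~ dxy, low Fst, positive Tajima's D, species non-monophyly.

The model deliberately violates infinite sites (finite L, resampling
allowed) so downstream statistics see realistic homoplasy.  In codon mode
the standard genetic code is used; a proposed change is kept with
probability 1 if synonymous, otherwise with probability omega, and changes
creating stop codons are always rejected (thinning, not rate rescaling).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .errors import ValidationError
from .io import GeneFeature, GenePanel, SpeciesAlignment

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

#: Newick stem length per unit of d_bal for the star-of-subtrees genealogy of
#: balanced loci; only the topology matters downstream, the scale just keeps
#: inter-lineage stems visibly longer than within-lineage coalescent heights.
_STEM_SCALE = 50.0


@dataclass
class SimConfig:
    """Simulation parameters (times in units of 2N generations)."""

    n_a: int = 10
    n_b: int = 10
    t_split: float = 5.0
    theta: float = 5.0  # per-locus 4*N*mu*L
    L: int = 500
    mode: str = "nucleotide"  # "nucleotide" | "codon"
    omega: float = 1.0  # nonsynonymous retention probability (codon mode)
    k: int = 2  # balanced allelic lineages
    d_bal: float = 0.3  # expected per-site founder divergence
    theta_within: float = 0.5
    seed: int = 0
    species_a: str = "speciesA"
    species_b: str = "speciesB"
    lineage_freqs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0 or self.n_a + self.n_b < 1:
            raise ValidationError("need at least one sampled strain")
        for name in ("t_split", "theta", "d_bal", "theta_within"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.L < 3:
            raise ValidationError("L must be >= 3")
        if self.mode not in ("nucleotide", "codon"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "codon" and self.L % 3 != 0:
            raise ValidationError("codon mode requires L to be a multiple of 3")
        if not (0.0 <= self.omega <= 1.0):
            raise ValidationError("omega must be in [0, 1]")
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.lineage_freqs is not None:
            if len(self.lineage_freqs) != self.k:
                raise ValidationError("lineage_freqs must have length k")
            if abs(sum(self.lineage_freqs) - 1.0) > 1e-9:
                raise ValidationError("lineage_freqs must sum to 1")


@dataclass
class SimulatedLocus:
    alignment: SpeciesAlignment
    genealogy: str
    truth_class_of: dict[str, int] | None
    is_balanced: bool

    def __post_init__(self) -> None:
        if self.is_balanced != (self.truth_class_of is not None):
            raise ValidationError(
                "truth_class_of must be present iff the locus is balanced"
            )


class _Node:
    __slots__ = ("children", "label", "height")

    def __init__(self, label=None, height=0.0, children=None):
        self.label = label
        self.height = height
        self.children = children or []


def _newick(node: _Node, parent_height: float | None = None) -> str:
    if node.children:
        inner = ",".join(_newick(c, node.height) for c in node.children)
        s = f"({inner})"
    else:
        s = node.label
    if parent_height is not None:
        s += f":{parent_height - node.height:.8f}"
    return s


def _coalesce(
    nodes: list[_Node], rng: np.random.Generator, start: float, stop: float | None
) -> tuple[list[_Node], float]:
    """Kingman coalescent on *nodes* from time *start* until one lineage
    remains or *stop* is reached (pair rate 1 per unit of 2N generations)."""
    t = start
    nodes = list(nodes)
    while len(nodes) > 1:
        j = len(nodes)
        dt = rng.exponential(1.0 / (j * (j - 1) / 2.0))
        if stop is not None and t + dt > stop:
            return nodes, stop
        t += dt
        i, jj = rng.choice(j, size=2, replace=False)
        i, jj = (int(i), int(jj)) if i < jj else (int(jj), int(i))
        parent = _Node(height=t, children=[nodes[i], nodes[jj]])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, jj)] + [parent]
    return nodes, t


def _random_sequence(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    if cfg.mode == "nucleotide":
        return list(rng.choice(list(_BASES), size=cfg.L))
    sense = sorted(set("".join(p) for p in _all_codons()) - _STOPS)
    codons = rng.choice(sense, size=cfg.L // 3)
    return list("".join(codons))


def _all_codons():
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                yield a + b + c


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def _apply_mutations(
    seq: list[str], n_mut: int, cfg: SimConfig, rng: np.random.Generator
) -> list[str]:
    """Apply n_mut proposed mutations; in codon mode nonsynonymous proposals
    are thinned by omega and stop-creating proposals always discarded."""
    seq = list(seq)
    for _ in range(n_mut):
        site = int(rng.integers(cfg.L))
        cur = seq[site]
        alt = cur
        while alt == cur:  # uniform over the three other bases
            alt = _BASES[int(rng.integers(4))]
        if cfg.mode == "codon":
            c0 = site - site % 3
            old_codon = "".join(seq[c0 : c0 + 3])
            new_codon = old_codon[: site - c0] + alt + old_codon[site - c0 + 1 :]
            if new_codon in _STOPS:
                continue
            if _translate_codon(new_codon) != _translate_codon(old_codon):
                if rng.random() >= cfg.omega:
                    continue
        seq[site] = alt
    return seq


def _drop_sequences(
    root: _Node, root_seq: list[str], cfg: SimConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Evolve sequences down the genealogy (preorder, deterministic order)."""
    out: dict[str, str] = {}
    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if not node.children:
            out[node.label] = "".join(seq)
            continue
        for child in reversed(node.children):
            blen = node.height - child.height
            n_mut = int(rng.poisson(cfg.theta / 2.0 * blen)) if blen > 0 else 0
            stack.append((child, _apply_mutations(seq, n_mut, cfg, rng)))
    return out


def _strain_labels(cfg: SimConfig) -> tuple[list[str], list[str]]:
    labels_a = [f"A{i + 1:03d}" for i in range(cfg.n_a)]
    labels_b = [f"B{i + 1:03d}" for i in range(cfg.n_b)]
    return labels_a, labels_b


def simulate_neutral_locus(cfg: SimConfig, gene_id: str = "locus") -> SimulatedLocus:
    """One neutral locus under the two-population split coalescent."""
    rng = np.random.default_rng(cfg.seed)
    labels_a, labels_b = _strain_labels(cfg)
    pool_a = [_Node(label=l) for l in labels_a]
    pool_b = [_Node(label=l) for l in labels_b]
    pool_a, _ = _coalesce(pool_a, rng, 0.0, cfg.t_split) if pool_a else (pool_a, 0.0)
    pool_b, _ = _coalesce(pool_b, rng, 0.0, cfg.t_split) if pool_b else (pool_b, 0.0)
    merged, _ = _coalesce(pool_a + pool_b, rng, cfg.t_split, None)
    root = merged[0]
    root_seq = _random_sequence(cfg, rng)
    seqs_by_label = _drop_sequences(root, root_seq, cfg, rng)
    order = labels_a + labels_b
    species_of = {l: cfg.species_a for l in labels_a}
    species_of.update({l: cfg.species_b for l in labels_b})
    aln = SpeciesAlignment(
        gene_id=gene_id,
        seqs={l: seqs_by_label[l] for l in order},
        alphabet="dna",
        species_of=species_of,
    )
    return SimulatedLocus(
        alignment=aln,
        genealogy=_newick(root) + ";",
        truth_class_of=None,
        is_balanced=False,
    )


def simulate_balanced_locus(cfg: SimConfig, gene_id: str = "locus") -> SimulatedLocus:
    """One locus with k trans-species allelic lineages under balancing
    selection (star-of-subtrees approximation, not a structured coalescent)."""
    if cfg.d_bal <= 0 and cfg.k >= 2:
        # degenerate but allowed: founders identical
        pass
    rng = np.random.default_rng(cfg.seed)
    labels_a, labels_b = _strain_labels(cfg)
    all_labels = labels_a + labels_b
    if cfg.k > len(all_labels):
        warnings.warn(
            f"k={cfg.k} lineages but only {len(all_labels)} strains: some "
            "lineages will be unsampled"
        )
    ancestor = _random_sequence(cfg, rng)
    founders = []
    for _ in range(cfg.k):
        n_sub = int(rng.binomial(cfg.L, cfg.d_bal)) if cfg.d_bal > 0 else 0
        seq = list(ancestor)
        sites = rng.choice(cfg.L, size=min(n_sub, cfg.L), replace=False)
        for site in sites:
            site = int(site)
            cur = seq[site]
            alt = cur
            while alt == cur:
                alt = _BASES[int(rng.integers(4))]
            if cfg.mode == "codon":
                c0 = site - site % 3
                old_codon = "".join(seq[c0 : c0 + 3])
                new_codon = (
                    old_codon[: site - c0] + alt + old_codon[site - c0 + 1 :]
                )
                if new_codon in _STOPS:
                    continue
                if _translate_codon(new_codon) != _translate_codon(old_codon):
                    if rng.random() >= cfg.omega:
                        continue
            seq[site] = alt
        founders.append(seq)
    if cfg.lineage_freqs is not None:
        lineage_of = {
            l: int(rng.choice(cfg.k, p=cfg.lineage_freqs)) for l in all_labels
        }
    else:
        lineage_of = {l: int(rng.integers(cfg.k)) for l in all_labels}
    within_cfg = replace(cfg, theta=cfg.theta_within)
    seqs: dict[str, str] = {}
    subtrees: list[str] = []
    stem = max(cfg.d_bal * _STEM_SCALE, 1e-6)
    for lineage in range(cfg.k):
        members = [l for l in all_labels if lineage_of[l] == lineage]
        if not members:
            continue
        if len(members) == 1:
            seqs[members[0]] = "".join(founders[lineage])
            subtrees.append(f"{members[0]}:{stem:.8f}")
            continue
        nodes = [_Node(label=m) for m in members]
        merged, _ = _coalesce(nodes, rng, 0.0, None)
        sub_root = merged[0]
        sub_seqs = _drop_sequences(sub_root, founders[lineage], within_cfg, rng)
        seqs.update(sub_seqs)
        subtrees.append(_newick(sub_root) + f":{stem:.8f}")
    species_of = {l: cfg.species_a for l in labels_a}
    species_of.update({l: cfg.species_b for l in labels_b})
    aln = SpeciesAlignment(
        gene_id=gene_id,
        seqs={l: seqs[l] for l in all_labels},
        alphabet="dna",
        species_of=species_of,
    )
    return SimulatedLocus(
        alignment=aln,
        genealogy="(" + ",".join(subtrees) + ");",
        truth_class_of=dict(lineage_of),
        is_balanced=True,
    )


def simulate_panel(
    n_neutral: int,
    n_balanced: int,
    cfg_neutral: SimConfig,
    cfg_balanced: SimConfig,
    seed: int,
) -> tuple[GenePanel, dict[str, SimulatedLocus]]:
    """A gene panel of neutral background genes plus balanced mating genes.

    Per-gene seeds derive from the master seed as ``seed + gene index`` so
    the panel is reproducible gene by gene.
    """
    if n_neutral + n_balanced == 0:
        raise ValidationError("panel must contain at least one gene")
    genes: dict[str, SpeciesAlignment] = {}
    category_of: dict[str, str] = {}
    tree_of: dict[str, str] = {}
    loci: dict[str, SimulatedLocus] = {}
    idx = 0
    for i in range(n_neutral):
        gid = f"busco{i + 1:04d}"
        locus = simulate_neutral_locus(
            dataclasses.replace(cfg_neutral, seed=seed + idx), gene_id=gid
        )
        genes[gid] = locus.alignment
        category_of[gid] = "background"
        tree_of[gid] = locus.genealogy
        loci[gid] = locus
        idx += 1
    for i in range(n_balanced):
        gid = f"mat{i + 1:02d}"
        locus = simulate_balanced_locus(
            dataclasses.replace(cfg_balanced, seed=seed + idx), gene_id=gid
        )
        genes[gid] = locus.alignment
        category_of[gid] = "mating"
        tree_of[gid] = locus.genealogy
        loci[gid] = locus
        idx += 1
    panel = GenePanel(genes=genes, category_of=category_of, tree_of=tree_of)
    return panel, loci


# ---------------------------------------------------------------------------
# Pheromone-region fixture


# One fixed codon per amino acid, chosen so concatenations of these codons
# contain no internal ATG and (checked pair by pair) no CAT, i.e. no start
# codon on either strand inside a planted ORF.
_CODON_FOR = {
    "M": "ATG", "D": "GAC", "E": "GAG", "R": "CGT", "C": "TGC", "V": "GTG",
    "I": "ATC", "A": "GCC", "S": "TCC", "T": "ACA", "G": "GGC", "K": "AAG",
    "F": "TTC", "P": "CCG", "Q": "CAG", "N": "AAC", "L": "CTC", "H": "CAC",
    "W": "TGG", "Y": "TAC",
}
_FILLER_AA = "GSKQNPF"


def _encode_orf(peptide: str) -> str:
    return "".join(_CODON_FOR[aa] for aa in peptide) + "TAA"


def _random_filler(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_FILLER_AA), size=n))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class PlantedOrf:
    orf_id: str
    start: int  # 1-based inclusive, forward axis, includes stop codon
    end: int
    strand: str
    label: str
    motif: str  # "CaaX" | "CpaX" | "none"
    expected_verdict: str  # "accepted" | "rejected"


def _build_fixture(rng: np.random.Generator):
    contig_len = 50_000
    truths: list[PlantedOrf] = []
    inserts: list[tuple[int, str]] = []  # (0-based offset, sequence)

    def plant(orf_id, start1, peptide, strand, label, motif, verdict):
        dna = _encode_orf(peptide)
        seq = dna if strand == "+" else _revcomp(dna)
        inserts.append((start1 - 1, seq))
        truths.append(
            PlantedOrf(
                orf_id=orf_id,
                start=start1,
                end=start1 + len(dna) - 1,
                strand=strand,
                label=label,
                motif=motif,
                expected_verdict=verdict,
            )
        )

    # two STE3 placeholder features (intervals only; their sequence is
    # ordinary background)
    features = [
        GeneFeature("contig1", 10_000, 11_200, "+", "STE3.2", kind="STE3"),
        GeneFeature("contig1", 30_000, 31_200, "+", "STE3.4", kind="STE3"),
    ]

    # true CaaX precursor, 126 bp, 2.2 kb downstream of STE3.2
    pep = "MD" + _random_filler(rng, 24) + "ER" + _random_filler(rng, 9) + "CVIA"
    plant("true_caax", 13_400, pep, "+", "true_caax", "CaaX", "accepted")

    # true CpaX precursor, 141 bp, reverse strand, 1.4 kb upstream of STE3.4
    pep = "MD" + _random_filler(rng, 28) + "DR" + _random_filler(rng, 10) + "CTIS"
    plant("true_cpax", 28_400, pep, "-", "true_cpax", "CpaX", "accepted")

    # decoys, each violating exactly one filter
    pep = "MD" + _random_filler(rng, 15) + "ER" + _random_filler(rng, 6) + "CVIA"
    plant("decoy_short", 16_000, pep, "+", "decoy_short_90bp", "CaaX", "rejected")

    pep = "MD" + _random_filler(rng, 52) + "ER" + _random_filler(rng, 9) + "CVIA"
    plant("decoy_long", 32_000, pep, "+", "decoy_long_210bp", "CaaX", "rejected")

    pep = "MD" + _random_filler(rng, 37) + "ER" + _random_filler(rng, 4) + "CGGS"
    plant("decoy_nomotif", 15_000, pep, "+", "decoy_no_motif", "none", "rejected")

    pep = "MD" + _random_filler(rng, 24) + "ER" + _random_filler(rng, 9) + "CVIA"
    plant("decoy_distant", 45_000, pep, "+", "decoy_distant_14kb", "CaaX", "rejected")

    # fill the rest of the contig base by base, never completing an ATG or
    # CAT triplet anywhere (so the planted ORFs are the only ORF starts)
    contig: list[str | None] = [None] * contig_len
    for off, seq in inserts:
        contig[off : off + len(seq)] = list(seq)
    forbidden = ("ATG", "CAT")
    for i in range(contig_len):
        if contig[i] is not None:
            continue
        order = list(rng.permutation(list(_BASES)))
        for b in order:
            contig[i] = b
            ok = True
            for w in range(max(0, i - 2), min(i, contig_len - 3) + 1):
                tri = contig[w : w + 3]
                if None not in tri and "".join(tri) in forbidden:
                    ok = False
                    break
            if ok:
                break
        else:
            contig[i] = "C"  # cannot happen: C never completes ATG/CAT here
    return "".join(contig), features, truths


def plant_pheromone_fixture(
    seed: int,
) -> tuple[str, list[GeneFeature], list[PlantedOrf]]:
    """A ~50 kb contig with planted pheromone-precursor ORFs near STE3
    features, plus decoys each violating exactly one scanner filter.

    The construction is verified against the scanner: the accepted set must
    be exactly the planted true precursors; if a random background draw
    breaks this (it essentially never does), the fixture is rebuilt from the
    next derived seed.
    """
    from . import pheromone  # deferred: pheromone does not import simulate

    for attempt in range(20):
        rng = np.random.default_rng(seed + 1_000_003 * attempt)
        contig, features, truths = _build_fixture(rng)
        hits = pheromone.scan_contig(contig, "contig1", features)
        accepted = {
            (h.orf_start, h.orf_end, h.strand)
            for h in hits
            if h.verdict == "accepted"
        }
        expected = {
            (t.start, t.end, t.strand)
            for t in truths
            if t.expected_verdict == "accepted"
        }
        if accepted == expected:
            return contig, features, truths
    raise RuntimeError("could not build a clean pheromone fixture")
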