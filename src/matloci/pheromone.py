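"""Pheromone-precursor detection near STE3 pheromone-receptor genes.

Candidate ORFs (100-200 bp including the stop codon, both strands) are
screened for a C-terminal prenylation signal: the canonical CaaX motif
(C = cysteine, a = aliphatic A/V/L/I, X = any residue) or the CpaX variant
in which position 2 carries a polar residue (threonine by default, as
observed in basidiomycete pheromone precursors).  The maturation site is
the rightmost ER or DR dipeptide strictly upstream of the motif cysteine;
the mature peptide runs from the residue after that R through the motif C
inclusive (typically 10-11 residues).  Hits far from any STE3 gene are
false positives and rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import ValidationError
from .io import GeneFeature

ALIPHATIC = frozenset("AVLI")
#: polar residues admitted at CaaX position 2 for the CpaX variant; only T
#: has been observed, {S,T,N,Q} is available for exploration
POLAR_DEFAULT = frozenset("T")
POLAR_EXTENDED = frozenset("STNQ")

_STOPS = {"TAA", "TAG", "TGA"}
_MATURE_RANGE = (8, 15)  # plausible mature-peptide length; outside -> warning


@dataclass
class PheromoneHit:
    contig: str
    orf_start: int  # 1-based inclusive, forward axis, includes stop codon
    orf_end: int
    strand: str
    orf_len_bp: int
    peptide: str
    motif_kind: str  # "CaaX" | "CpaX" | "none"
    motif_residues: str
    maturation_site: str  # "ER" | "DR" | "none"
    maturation_pos: int | None  # 1-based residue index of the E/D
    mature_peptide: str
    mature_len: int
    nearest_ste3_id: str | None
    nearest_ste3_distance: int | None
    filters_passed: list[str] = field(default_factory=list)
    verdict: str = "candidate"
    warnings_: list[str] = field(default_factory=list)


def find_orfs(
    contig_seq: str, min_bp: int = 100, max_bp: int = 200
) -> list[tuple[int, int, str, str]]:
    """All ATG->stop ORFs on both strands with min_bp <= length <= max_bp
    (length includes the stop codon).  Nested ORFs are reported
    independently.  Returns (start, end, strand, orf_dna) with 1-based
    inclusive forward-axis coordinates.
    """
    seq = contig_seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"non-DNA characters in contig: {sorted(bad)}")
    n = len(seq)
    out = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            for j in range(i + 3, n - 2, 3):
                codon = s[j : j + 3]
                if codon in _STOPS:
                    length = j + 3 - i
                    if min_bp <= length <= max_bp:
                        if strand == "+":
                            start, end = i + 1, j + 3
                        else:
                            start, end = n - (j + 3) + 1, n - i
                        out.append((start, end, strand, s[i : j + 3]))
                    break
    out.sort(key=lambda t: (t[0], t[2], t[1]))
    return out


def scan_precursor(
    peptide: str, polar: frozenset[str] = POLAR_DEFAULT
) -> dict:
    """Classify the C-terminal motif of a candidate precursor peptide and
    locate its maturation site.

    The peptide excludes the stop codon.  Peptides shorter than 6 residues
    cannot carry a motif plus maturation site and are classed ``none``.
    """
    res = {
        "motif_kind": "none",
        "motif_residues": peptide[-4:] if len(peptide) >= 4 else peptide,
        "maturation_site": "none",
        "maturation_pos": None,
        "mature_peptide": "",
        "mature_len": 0,
    }
    if len(peptide) < 6:
        return res
    last4 = peptide[-4:]
    c_index = len(peptide) - 4  # the motif cysteine
    if last4[0] == "C" and last4[2] in ALIPHATIC:
        if last4[1] in ALIPHATIC:
            res["motif_kind"] = "CaaX"
        elif last4[1] in polar:
            res["motif_kind"] = "CpaX"
    if res["motif_kind"] == "none":
        return res
    # rightmost ER/DR dipeptide strictly upstream of the motif cysteine
    for i in range(c_index - 2, -1, -1):
        if peptide[i : i + 2] in ("ER", "DR"):
            res["maturation_site"] = peptide[i : i + 2]
            res["maturation_pos"] = i + 1
            res["mature_peptide"] = peptide[i + 2 : c_index + 1]
            res["mature_len"] = len(res["mature_peptide"])
            break
    return res


def _interval_gap(s1: int, e1: int, s2: int, e2: int) -> int:
    """Bases strictly between two 1-based inclusive intervals (0 if they
    touch or overlap)."""
    return max(0, max(s1 - e2, s2 - e1) - 1)


def proximity_filter(
    hits: list[PheromoneHit],
    ste3_features: list[GeneFeature],
    max_dist_bp: int = 5000,
) -> list[PheromoneHit]:
    """Assign verdicts: accepted iff a motif is present and the ORF lies
    within max_dist_bp of an STE3 feature on the same contig (the length
    filter was already applied by the ORF finder)."""
    ste3 = [f for f in ste3_features if f.kind == "STE3"]
    for hit in hits:
        same = [f for f in ste3 if f.contig == hit.contig]
        if not same:
            warnings.warn(
                f"no STE3 features on contig {hit.contig}: all hits rejected"
            )
            hit.nearest_ste3_id = None
            hit.nearest_ste3_distance = None
            hit.verdict = "rejected(distance)"
            continue
        dists = [
            (_interval_gap(hit.orf_start, hit.orf_end, f.start, f.end), f.feature_id)
            for f in same
        ]
        dist, fid = min(dists)
        hit.nearest_ste3_id = fid
        hit.nearest_ste3_distance = dist
        hit.filters_passed.append("length")
        if hit.motif_kind == "none":
            hit.verdict = "rejected(no-motif)"
            continue
        hit.filters_passed.append("motif")
        if dist > max_dist_bp:
            hit.verdict = "rejected(distance)"
            continue
        hit.filters_passed.append("proximity")
        hit.verdict = "accepted"
        if not (_MATURE_RANGE[0] <= hit.mature_len <= _MATURE_RANGE[1]):
            hit.warnings_.append(
                f"mature peptide length {hit.mature_len} outside "
                f"{_MATURE_RANGE}"
            )
    return hits


def scan_contig(
    contig_seq: str,
    contig_name: str,
    ste3_features: list[GeneFeature],
    min_bp: int = 100,
    max_bp: int = 200,
    max_dist_bp: int = 5000,
    polar: frozenset[str] = POLAR_DEFAULT,
) -> list[PheromoneHit]:
    """Full scan of one contig: ORF finding, motif/maturation annotation and
    the STE3 proximity filter.  Output is sorted by (contig, start, strand)."""
    hits = []
    for start, end, strand, orf_dna in find_orfs(contig_seq, min_bp, max_bp):
        peptide = str(Seq(orf_dna[:-3]).translate())
        ann = scan_precursor(peptide, polar=polar)
        hits.append(
            PheromoneHit(
                contig=contig_name,
                orf_start=start,
                orf_end=end,
                strand=strand,
                orf_len_bp=len(orf_dna),
                peptide=peptide,
                motif_kind=ann["motif_kind"],
                motif_residues=ann["motif_residues"],
                maturation_site=ann["maturation_site"],
                maturation_pos=ann["maturation_pos"],
                mature_peptide=ann["mature_peptide"],
                mature_len=ann["mature_len"],
                nearest_ste3_id=None,
                nearest_ste3_distance=None,
            )
        )
    hits = proximity_filter(hits, ste3_features, max_dist_bp=max_dist_bp)
    hits.sort(key=lambda h: (h.contig, h.orf_start, h.strand))
    return hits
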