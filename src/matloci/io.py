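"""Readers, writers and the shared in-memory data model.

All file formats use 1-based inclusive coordinates (GFF3 convention); every
internal column index is 0-based half-open.  The conversion between the two
is confined to this module.  The only gap character accepted is ``'-'``
(``'.'`` is rejected); ``N`` (DNA) and ``X`` (protein) are carried through
and treated as missing data by the statistics modules.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

DNA_RESIDUES = frozenset("ACGTN-")
PROTEIN_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX-")
GENE_CATEGORIES = ("mating", "flanking", "background")

#: fixed columns of the strain metadata table; extra columns are preserved
#: by :func:`read_strain_table` but ignored everywhere else.
STRAIN_TABLE_COLUMNS = ("strain_id", "species", "specimen_id", "continent")


@dataclass
class SpeciesAlignment:
    """A per-gene multiple alignment with strain -> species labels.

    This is the unit every statistic consumes: the trimmed, codon-based
    (or protein) alignment of one gene across all sequenced strains of the
    two sister species.
    """

    gene_id: str
    seqs: dict[str, str]
    alphabet: str = "dna"  # "dna" | "protein"
    species_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        if not self.seqs:
            raise ValidationError(f"gene {self.gene_id}: empty alignment")
        lengths = {s: len(seq) for s, seq in self.seqs.items()}
        if len(set(lengths.values())) > 1:
            raise ValidationError(
                f"gene {self.gene_id}: unequal sequence lengths {lengths}"
            )
        allowed = DNA_RESIDUES if self.alphabet == "dna" else PROTEIN_RESIDUES
        for strain, seq in self.seqs.items():
            for pos, ch in enumerate(seq):
                if ch not in allowed:
                    raise ValidationError(
                        f"gene {self.gene_id}, strain {strain}: illegal "
                        f"{self.alphabet} residue {ch!r} at column {pos}"
                    )
        missing = [s for s in self.seqs if s not in self.species_of]
        if missing:
            raise ValidationError(
                f"gene {self.gene_id}: strains without species label: {missing}"
            )

    @property
    def strains(self) -> list[str]:
        return list(self.seqs)

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values())))

    def strains_of(self, species: str) -> list[str]:
        return [s for s in self.seqs if self.species_of[s] == species]

    def subset(self, strains: Iterable[str]) -> "SpeciesAlignment":
        strains = list(strains)
        return SpeciesAlignment(
            gene_id=self.gene_id,
            seqs={s: self.seqs[s] for s in strains},
            alphabet=self.alphabet,
            species_of={s: self.species_of[s] for s in strains},
        )

    def translated(self) -> "SpeciesAlignment":
        """Translate an in-frame codon alignment to protein.

        Codons made entirely of gaps become ``-``; codons containing a gap
        or ``N`` become ``X``.  Internal stop codons raise.
        """
        if self.alphabet != "dna":
            raise ValidationError("translated() requires a DNA alignment")
        if self.length % 3 != 0:
            raise ValidationError(
                f"gene {self.gene_id}: length {self.length} not a multiple of 3"
            )
        out = {}
        for strain, seq in self.seqs.items():
            aas = []
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if codon == "---":
                    aas.append("-")
                elif "-" in codon or "N" in codon:
                    aas.append("X")
                else:
                    aa = str(Seq(codon).translate())
                    if aa == "*":
                        raise ValidationError(
                            f"gene {self.gene_id}, strain {strain}: internal "
                            f"stop codon at nucleotide column {i}"
                        )
                    aas.append(aa)
            out[strain] = "".join(aas)
        return SpeciesAlignment(
            gene_id=self.gene_id,
            seqs=out,
            alphabet="protein",
            species_of=dict(self.species_of),
        )


@dataclass
class GenePanel:
    """A collection of per-gene alignments plus the mating/flanking/background
    partition and optional per-gene Newick trees."""

    genes: dict[str, SpeciesAlignment]
    category_of: dict[str, str]
    tree_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid in self.genes:
            cat = self.category_of.get(gid)
            if cat is None:
                raise ValidationError(f"gene {gid}: no category assigned")
            if cat not in GENE_CATEGORIES:
                raise ValidationError(
                    f"gene {gid}: unknown category {cat!r} "
                    f"(expected one of {GENE_CATEGORIES})"
                )
        extra = set(self.tree_of) - set(self.genes)
        if extra:
            raise ValidationError(f"trees for unknown genes: {sorted(extra)}")

    def gene_ids(self, category: str | None = None) -> list[str]:
        if category is None:
            return list(self.genes)
        return [g for g in self.genes if self.category_of[g] == category]


@dataclass
class GeneFeature:
    """A genomic interval (1-based inclusive) used by the pheromone scanner."""

    contig: str
    start: int
    end: int
    strand: str
    feature_id: str
    kind: str = "other"  # "STE3" | "ORF" | "other"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"feature {self.feature_id}: bad interval {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"feature {self.feature_id}: bad strand {self.strand!r}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str, alphabet: str = "dna", aligned: bool = True) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered ``id -> uppercased sequence`` map.

    Raises :class:`FormatError` on duplicate ids, on unequal lengths when an
    alignment is expected, and on illegal residues (position reported).
    """
    if not os.path.exists(path):
        raise FormatError(f"FASTA file not found: {path}")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    allowed = DNA_RESIDUES if alphabet == "dna" else PROTEIN_RESIDUES
    for sid, seq in seqs.items():
        for pos, ch in enumerate(seq):
            if ch not in allowed:
                raise FormatError(
                    f"{path}: record {sid!r} has illegal {alphabet} residue "
                    f"{ch!r} at position {pos + 1}"
                )
    if aligned:
        lengths = {sid: len(s) for sid, s in seqs.items()}
        if len(set(lengths.values())) > 1:
            raise FormatError(f"{path}: unequal aligned lengths: {lengths}")
    return seqs


def write_fasta(path: str, seqs: Mapping[str, str], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Newick


def read_newick(path_or_text: str) -> dendropy.Tree:
    """Parse Newick from a file path or a literal string.

    Leaf labels are preserved verbatim (underscores kept); absent branch
    lengths stay ``None``.  Duplicate leaf labels raise :class:`FormatError`.
    """
    if "(" in path_or_text:
        src = {"data": path_or_text}
    else:
        if not os.path.exists(path_or_text):
            raise FormatError(f"Newick file not found: {path_or_text}")
        src = {"path": path_or_text}
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            **src,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels in Newick: {sorted(dupes)}")
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Strain metadata and gene-panel manifest


def read_strain_table(path: str) -> pd.DataFrame:
    """Read the strain metadata TSV (strain_id, species, specimen_id,
    continent; extra columns preserved)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in STRAIN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing strain-table columns {missing}")
    if df["strain_id"].duplicated().any():
        dupes = df.loc[df["strain_id"].duplicated(), "strain_id"].tolist()
        raise FormatError(f"{path}: duplicate strain_id rows: {dupes}")
    return df


def species_map(strain_table: pd.DataFrame) -> dict[str, str]:
    return dict(zip(strain_table["strain_id"], strain_table["species"]))


def read_gene_panel(
    manifest_path: str, strain_table: pd.DataFrame | str
) -> GenePanel:
    """Load a full :class:`GenePanel` from a manifest TSV.

    Manifest columns: ``gene_id``, ``fasta_path``, ``category`` and optional
    ``newick_path``; relative paths resolve against the manifest directory.
    """
    if isinstance(strain_table, str):
        strain_table = read_strain_table(strain_table)
    sp_of = species_map(strain_table)
    base = os.path.dirname(os.path.abspath(manifest_path))
    mf = pd.read_csv(manifest_path, sep="\t", dtype=str)
    for col in ("gene_id", "fasta_path", "category"):
        if col not in mf.columns:
            raise FormatError(f"{manifest_path}: missing manifest column {col!r}")
    genes: dict[str, SpeciesAlignment] = {}
    category_of: dict[str, str] = {}
    tree_of: dict[str, str] = {}
    for row in mf.itertuples(index=False):
        gid = row.gene_id
        if gid in genes:
            raise FormatError(f"{manifest_path}: duplicate gene_id {gid!r}")
        if row.category not in GENE_CATEGORIES:
            raise FormatError(
                f"{manifest_path}: gene {gid}: unknown category {row.category!r}"
            )
        fpath = row.fasta_path
        if not os.path.isabs(fpath):
            fpath = os.path.join(base, fpath)
        if not os.path.exists(fpath):
            raise FormatError(f"{manifest_path}: gene {gid}: missing FASTA {fpath}")
        seqs = read_fasta(fpath, alphabet="dna", aligned=True)
        unknown = [s for s in seqs if s not in sp_of]
        if unknown:
            raise FormatError(
                f"{manifest_path}: gene {gid}: strains absent from the "
                f"metadata table: {unknown}"
            )
        genes[gid] = SpeciesAlignment(
            gene_id=gid,
            seqs=seqs,
            alphabet="dna",
            species_of={s: sp_of[s] for s in seqs},
        )
        category_of[gid] = row.category
        npath = getattr(row, "newick_path", None)
        if isinstance(npath, str) and npath and npath.lower() != "nan":
            if not os.path.isabs(npath):
                npath = os.path.join(base, npath)
            if not os.path.exists(npath):
                raise FormatError(
                    f"{manifest_path}: gene {gid}: missing Newick {npath}"
                )
            with open(npath) as fh:
                tree_of[gid] = fh.read().strip()
    return GenePanel(genes=genes, category_of=category_of, tree_of=tree_of)


# ---------------------------------------------------------------------------
# GFF3-style features


def read_features(path: str) -> list[GeneFeature]:
    """Read GFF3 (9-column, 1-based inclusive) into :class:`GeneFeature`s.

    The feature ``type`` column becomes ``kind`` when it is ``STE3`` or
    ``ORF``; anything else maps to ``other``.  The ``ID`` attribute (or a
    synthesized name) becomes ``feature_id``.
    """
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            fid = f"{ftype}_{ln}"
            for token in attrs.split(";"):
                if token.startswith("ID="):
                    fid = token[3:]
            kind = ftype if ftype in ("STE3", "ORF") else "other"
            feats.append(
                GeneFeature(
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    feature_id=fid,
                    kind=kind,
                )
            )
    return feats


def write_features(path: str, feats: Iterable[GeneFeature], source: str = "matloci") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            fh.write(
                "\t".join(
                    [
                        f.contig,
                        source,
                        f.kind if f.kind != "other" else "region",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id}",
                    ]
                )
                + "\n"
            )
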