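"""Mating genotypes, type enumeration, cross compatibility and parental
(dikaryon) genotype unfolding.

In a tetrapolar system the MATA locus holds two homeodomain complexes
(alpha = aHD1+aHD2, beta = bHD1+bHD2) and the MATB locus two mating
pheromone receptors (STE3.2, STE3.4).  A *complex class* is the joint
(HD1, HD2) pair of allelic-class labels, compared as a tuple.  Two
monokaryons are predicted compatible when at least one MATA complex
(alpha or beta) AND at least one receptor (STE3.2 or STE3.4) differ.
Predicted type counts use free combinatorics (products of component class
counts), the field's own convention, even though linked HD pairs cannot
recombine freely within a complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .allelic import AllelicClassification
from .errors import ValidationError

#: the six mating genes, keyed by role
MATING_GENES = ("aHD1", "aHD2", "bHD1", "bHD2", "STE3.2", "STE3.4")
MATA_GENES = ("aHD1", "aHD2", "bHD1", "bHD2")
MATB_GENES = ("STE3.2", "STE3.4")


@dataclass
class MatingGenotype:
    strain_id: str
    species: str
    alpha: tuple[int, int] | None  # (aHD1 class, aHD2 class)
    beta: tuple[int, int] | None  # (bHD1 class, bHD2 class)
    ste32: int | None
    ste34: int | None
    gene_classes: dict[str, int] = field(default_factory=dict)
    missing_reasons: dict[str, str] = field(default_factory=dict)

    @property
    def typeable(self) -> bool:
        return (self.alpha is not None or self.beta is not None) and (
            self.ste32 is not None or self.ste34 is not None
        )

    @property
    def mata(self) -> tuple | None:
        if self.alpha is None or self.beta is None:
            return None
        return (self.alpha, self.beta)

    @property
    def matb(self) -> tuple | None:
        if self.ste32 is None or self.ste34 is None:
            return None
        return (self.ste32, self.ste34)


@dataclass
class TypeCensus:
    scope: str  # species name or "pooled"
    n_strains: int
    n_alpha: int
    n_beta: int
    n_ste32: int
    n_ste34: int
    observed_mata: int
    observed_matb: int
    observed_types: int

    @property
    def n_mata(self) -> int:
        return self.n_alpha * self.n_beta

    @property
    def n_matb(self) -> int:
        return self.n_ste32 * self.n_ste34

    @property
    def n_types(self) -> int:
        return self.n_mata * self.n_matb


def assign_genotypes(
    classifications: Mapping[str, AllelicClassification],
    species_of: Mapping[str, str],
) -> list[MatingGenotype]:
    """One genotype per strain from per-gene allelic classifications.

    ``classifications`` is keyed by gene role (:data:`MATING_GENES`); genes
    absent for a strain (e.g. a lost bHD1) leave the affected complex
    missing, with the reason recorded.  Strains present in no
    classification are excluded with a warning.
    """
    unknown = [g for g in classifications if g not in MATING_GENES]
    if unknown:
        raise ValidationError(f"unknown mating gene roles: {unknown}")
    strains: list[str] = []
    for cls in classifications.values():
        for s in cls.class_of:
            if s not in strains:
                strains.append(s)
    out = []
    for s in strains:
        if s not in species_of:
            warnings.warn(f"strain {s}: no species label; excluded")
            continue
        gc: dict[str, int] = {}
        reasons: dict[str, str] = {}
        for gene in MATING_GENES:
            cls = classifications.get(gene)
            if cls is None or s not in cls.class_of:
                reasons[gene] = "gene absent for strain"
            else:
                gc[gene] = cls.class_of[s]

        def pair(g1: str, g2: str) -> tuple[int, int] | None:
            if g1 in gc and g2 in gc:
                return (gc[g1], gc[g2])
            return None

        out.append(
            MatingGenotype(
                strain_id=s,
                species=species_of[s],
                alpha=pair("aHD1", "aHD2"),
                beta=pair("bHD1", "bHD2"),
                ste32=gc.get("STE3.2"),
                ste34=gc.get("STE3.4"),
                gene_classes=gc,
                missing_reasons=reasons,
            )
        )
    return out


def enumerate_types(
    genotypes: Iterable[MatingGenotype], scope: str = "pooled"
) -> TypeCensus:
    """Census of observed component classes and predicted type products.

    ``scope`` is a species name or ``"pooled"``.  Strains missing a
    component are excluded from that component's census only.
    """
    gts = [
        g
        for g in genotypes
        if scope == "pooled" or g.species == scope
    ]
    typeable = [g for g in gts if g.typeable]
    if not typeable:
        raise ValidationError(f"no typeable strains in scope {scope!r}")
    alphas = {g.alpha for g in gts if g.alpha is not None}
    betas = {g.beta for g in gts if g.beta is not None}
    s32 = {g.ste32 for g in gts if g.ste32 is not None}
    s34 = {g.ste34 for g in gts if g.ste34 is not None}
    mata = {g.mata for g in gts if g.mata is not None}
    matb = {g.matb for g in gts if g.matb is not None}
    full = {
        (g.mata, g.matb) for g in gts if g.mata is not None and g.matb is not None
    }
    return TypeCensus(
        scope=scope,
        n_strains=len(gts),
        n_alpha=len(alphas),
        n_beta=len(betas),
        n_ste32=len(s32),
        n_ste34=len(s34),
        observed_mata=len(mata),
        observed_matb=len(matb),
        observed_types=len(full),
    )


def predict_compatibility(
    g1: MatingGenotype, g2: MatingGenotype
) -> tuple[str, str]:
    """Predict the outcome of a cross: ``compatible``, ``incompatible`` or
    ``indeterminate``, with the components that decided it.

    A cross is compatible iff (alpha differs OR beta differs) AND
    (STE3.2 differs OR STE3.4 differs); "differs" requires both values
    present and unequal.  When the decision hinges on a missing component
    the verdict is indeterminate.  Genotypic compatibility between species
    is necessary but not sufficient (pre-zygotic barriers); such calls
    carry a cautionary note in the reason.
    """

    def cmp(v1, v2) -> str:
        if v1 is None or v2 is None:
            return "unknown"
        return "differs" if v1 != v2 else "same"

    mata = {
        "alpha": cmp(g1.alpha, g2.alpha),
        "beta": cmp(g1.beta, g2.beta),
    }
    matb = {
        "STE3.2": cmp(g1.ste32, g2.ste32),
        "STE3.4": cmp(g1.ste34, g2.ste34),
    }

    def side(results: dict[str, str]) -> str:
        if any(v == "differs" for v in results.values()):
            return "true"
        if all(v == "same" for v in results.values()):
            return "false"
        return "unknown"

    sa, sb = side(mata), side(matb)
    detail = (
        "MATA[" + ", ".join(f"{k}:{v}" for k, v in mata.items()) + "]; "
        "MATB[" + ", ".join(f"{k}:{v}" for k, v in matb.items()) + "]"
    )
    if sa == "false" or sb == "false":
        verdict = "incompatible"
    elif sa == "true" and sb == "true":
        verdict = "compatible"
    else:
        verdict = "indeterminate"
    if verdict == "compatible" and g1.species != g2.species:
        detail += (
            "; inter-species cross: genotypic compatibility is necessary, "
            "not sufficient"
        )
    return verdict, detail


@dataclass
class ParentalUnfold:
    """Inferred allelic-class composition of the parental dikaryon from
    sibling monokaryons of one specimen."""

    classes_by_gene: dict[str, set[int]]
    complete_by_gene: dict[str, bool]
    complete: bool
    resolved: bool  # False when < 2 siblings were available


def unfold_parental(siblings: list[MatingGenotype]) -> ParentalUnfold:
    """Per-gene sets of classes observed among sibling monokaryons.

    A dikaryotic parent carries at most two alleles per gene: more than two
    distinct classes among siblings is an inconsistency error.  The
    unfolding is complete when two distinct classes were recovered for the
    MATA components and the MATB components.
    """
    if not siblings:
        raise ValidationError("unfold_parental requires at least one sibling")
    classes: dict[str, set[int]] = {}
    for g in siblings:
        for gene, cls in g.gene_classes.items():
            classes.setdefault(gene, set()).add(cls)
    for gene, vals in classes.items():
        if len(vals) > 2:
            raise ValidationError(
                f"gene {gene}: {len(vals)} distinct classes among siblings "
                f"({sorted(vals)}) violates a single-dikaryon origin"
            )
    complete_by_gene = {g: len(v) == 2 for g, v in classes.items()}
    mata_complete = all(
        complete_by_gene.get(g, False) for g in MATA_GENES if g in classes
    ) and any(g in classes for g in MATA_GENES)
    matb_complete = all(
        complete_by_gene.get(g, False) for g in MATB_GENES if g in classes
    ) and any(g in classes for g in MATB_GENES)
    resolved = len(siblings) >= 2
    if not resolved:
        warnings.warn(
            "fewer than 2 siblings: parental composition necessarily unresolved"
        )
    return ParentalUnfold(
        classes_by_gene=classes,
        complete_by_gene=complete_by_gene,
        complete=mata_complete and matb_complete and resolved,
        resolved=resolved,
    )
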