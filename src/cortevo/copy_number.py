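"""Comparative-Ct copy-number estimation and amplicon read assignment.

Cross-species relative gene-family copy number is estimated from genomic
qPCR cycle-threshold (Ct) tables by the comparative-Ct method: Ct values of
each target family are normalized to a conserved single-copy gene (STX12 in
the study) within each species, the normalized values are compared against
a reference species (bonobo), and the cycle difference is converted to a
fold ratio via the amplification efficiency E (default 2.0, perfect
doubling per cycle):

    estimate(s) = E ** -( dCt(s) - dCt(ref_species) ),
    dCt(s) = mean Ct(target, s) - mean Ct(normalizer, s).

Cross-species primer compatibility follows the study's rule of at most one
mismatch in the primer binding site, and amplicon sequencing reads are
assigned to target loci by unique best-hit matching with a specificity
percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import pandas as pd

from .paralog_expression import reverse_complement


@dataclass
class CtTable:
    """Replicate Ct measurements keyed by (gene group, species).

    ``data`` has columns ``gene_group``, ``species``, ``replicate``,
    ``ct``.  ``ref_gene`` is the single-copy normalizer present in every
    species; ``ref_species`` anchors the relative scale at 1.0.
    """

    data: pd.DataFrame
    ref_gene: str = "STX12"
    ref_species: str = "bonobo"
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        required = {"gene_group", "species", "replicate", "ct"}
        if not required <= set(self.data.columns):
            raise ValueError(f"Ct table lacks columns {sorted(required - set(self.data.columns))}")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("amplification efficiency must lie in (1, 2]")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        species = set(self.data["species"].unique())
        ref_rows = self.data[self.data["gene_group"] == self.ref_gene]
        missing = species - set(ref_rows["species"].unique())
        if missing:
            raise ValueError(
                f"normalizer {self.ref_gene!r} missing for species {sorted(missing)}"
            )
        if self.ref_species not in species:
            raise ValueError(f"reference species {self.ref_species!r} absent")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)


@dataclass(frozen=True)
class CopyNumberEstimate:
    gene_group: str
    species: str
    relative_copy_number: float
    replicate_sd: float  # sd of the target Ct replicates, in cycles

    def __post_init__(self) -> None:
        if self.relative_copy_number <= 0:
            raise ValueError("copy-number estimates are strictly positive")


def relative_copy_number(
    table: CtTable, aggregate: str = "mean"
) -> list[CopyNumberEstimate]:
    """Comparative-Ct estimates for every (target, species) in the table.

    Replicates are aggregated by ``aggregate`` ("mean", the standard
    choice, or "median") before forming delta-Ct.  The reference species'
    estimate is exactly 1 for every target by construction.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    agg = table.data.groupby(["gene_group", "species"])["ct"].agg(aggregate)
    sd = table.data.groupby(["gene_group", "species"])["ct"].std(ddof=0)
    targets = sorted(set(table.data["gene_group"].unique()) - {table.ref_gene})
    species = sorted(table.data["species"].unique())
    out: list[CopyNumberEstimate] = []
    for target in targets:
        missing = [s for s in species if (target, s) not in agg.index]
        if missing:
            raise ValueError(f"target {target!r} lacks measurements for {missing}")
        dct = {s: agg[(target, s)] - agg[(table.ref_gene, s)] for s in species}
        ref_dct = dct[table.ref_species]
        for s in species:
            estimate = float(table.efficiency ** -(dct[s] - ref_dct))
            out.append(
                CopyNumberEstimate(
                    gene_group=target,
                    species=s,
                    relative_copy_number=estimate,
                    replicate_sd=float(sd[(target, s)]),
                )
            )
    return out


def estimates_frame(estimates: Sequence[CopyNumberEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_group": e.gene_group,
                "species": e.species,
                "relative_copy_number": e.relative_copy_number,
                "replicate_sd": e.replicate_sd,
            }
            for e in estimates
        ]
    )


def primer_compatibility(
    primer: str, binding_sites: Mapping[str, str], max_mismatches: int = 1
) -> dict[str, dict]:
    """Per-species primer verdicts under the <=1-mismatch rule.

    Each binding site must have the primer's length; the verdict counts
    Hamming mismatches and accepts at most ``max_mismatches`` (default 1,
    the study's rule).
    """
    primer = primer.upper()
    out = {}
    for species, site in binding_sites.items():
        site = site.upper()
        if len(site) != len(primer):
            raise ValueError(
                f"{species}: binding site length {len(site)} != primer length {len(primer)}"
            )
        mismatches = sum(a != b for a, b in zip(primer, site))
        out[species] = {
            "mismatches": mismatches,
            "compatible": mismatches <= max_mismatches,
        }
    return out


def _best_infix_distance(read: str, locus: str) -> int:
    """Best edit distance of ``read`` against any infix of ``locus``, both strands."""
    d_fwd = edlib.align(read, locus, mode="HW", task="distance")["editDistance"]
    d_rev = edlib.align(reverse_complement(read), locus, mode="HW", task="distance")[
        "editDistance"
    ]
    return min(d for d in (d_fwd, d_rev) if d >= 0)


def amplicon_assignment(
    reads: Sequence[str],
    loci: Mapping[str, str],
    max_mismatches: int = 0,
) -> dict:
    """Assign amplicon sequencing reads to target loci.

    A read is assigned to the locus with the strictly best infix edit
    distance (either strand) at most ``max_mismatches``; reads tied
    between loci are dropped from per-locus counts but stay in the library
    size.  Returns per-locus counts, the library size and the specificity
    percentage (assigned / total * 100).
    """
    names = list(loci)
    if len(set(loci.values())) != len(names):
        raise ValueError("duplicate locus sequences")
    counts = {name: 0 for name in names}
    assigned = 0
    for read in reads:
        read = read.upper()
        dists = {name: _best_infix_distance(read, loci[name].upper()) for name in names}
        best = min(dists.values())
        if best > max_mismatches:
            continue
        winners = [name for name, d in dists.items() if d == best]
        if len(winners) != 1:
            continue
        counts[winners[0]] += 1
        assigned += 1
    total = len(reads)
    return {
        "counts": counts,
        "library_size": total,
        "assigned": assigned,
        "specificity": (assigned / total * 100.0) if total else 0.0,
    }


#: qPCR family designs of the duplication-validation assay: for each gene
#: family, the human-specific paralogs co-amplified alongside the ancestral
#: gene.  Families marked cnpc=False are amplified by the assay but are not
#: part of the progenitor-enriched catalogue (GTF2H2B).
QPCR_FAMILIES: dict[str, dict] = {
    "ARHGAP11": {"ancestral": "ARHGAP11A", "fixture_prefix": "ARHGAP11", "extra": []},
    "FAM72": {"ancestral": "FAM72A", "fixture_prefix": "FAM72", "extra": []},
    "GTF2H2": {"ancestral": "GTF2H2", "fixture_prefix": "GTF2H2", "extra": ["GTF2H2B"]},
    "SMN": {"ancestral": "SMN1", "fixture_prefix": "SMN", "extra": []},
}


def family_copy_numbers(
    records, family: str, species: Sequence[str] = ("human", "chimpanzee", "bonobo")
) -> dict[str, int]:
    """Integer copy configuration of a validated gene family per species.

    The human copy count is 1 (ancestral gene) plus the human-specific
    members of the family found in the catalogue plus any co-amplified
    human-specific paralogs outside the catalogue; all other species carry
    the single ancestral copy.
    """
    design = QPCR_FAMILIES[family]
    human_specific = [
        r
        for r in records
        if r.occurrence == "Homo" and r.symbol.startswith(design["fixture_prefix"])
    ]
    n_human = 1 + len(human_specific) + len(design["extra"])
    return {s: (n_human if s == "human" else 1) for s in species}
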