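"""Gene distribution across ZOTUs and the modular Fe oxidation pathway model.

A ZOTU (Zetaproteobacteria operational taxonomic unit) groups genome bins
into a 16S-defined lineage.  Occupancy is the fraction of a ZOTU's genomes
possessing a gene label (presence = at least one copy).  The pathway model
treats Fe oxidation as four modules, each satisfied by any of several
alternative genes:

* Fe oxidase — cyc2 (Cluster 1 or Cluster 3 homologs)
* periplasmic electron carrier — cyc1 or an alternative cytochrome c
* complex III (reverse electron transport) — bc1 or alternative complex III
* terminal oxidase — cbb3 (proximal or distal), aa3, or bd-I

Because incomplete genome bins cause false-negative gene calls, ZOTU-level
module presence is reported both per genome and as a >=0.5 majority vote
across the ZOTU's genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import GenomeBin

logger = logging.getLogger(__name__)

DEFAULT_PATHWAY_MODEL: dict[str, frozenset[str]] = {
    "Fe_oxidase": frozenset({"cyc2_cluster1", "cyc2_cluster3"}),
    "electron_carrier": frozenset({"cyc1", "PC2", "PC3", "PC12", "PC16", "PC38", "PC61"}),
    "complex_III": frozenset({"bc1", "ACIII"}),
    "terminal_oxidase": frozenset({"cbb3_proximal", "cbb3_distal", "aa3", "bd1"}),
}

MAJORITY_FRACTION = 0.5


@dataclass
class GenomeCatalog:
    """Genome bins with ZOTU assignments, a label universe, and a pathway model."""

    bins: list[GenomeBin]
    pathway_model: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_PATHWAY_MODEL)
    )
    label_universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        observed = frozenset(l for b in self.bins for l in b.gene_labels)
        modeled = frozenset(l for labels in self.pathway_model.values() for l in labels)
        if not self.label_universe:
            self.label_universe = observed | modeled
        assigned: dict[str, str] = {}
        for module, labels in self.pathway_model.items():
            for label in labels:
                if label in assigned:
                    raise ValueError(
                        f"label {label!r} assigned to both {assigned[label]!r} and {module!r}"
                    )
                assigned[label] = module
        stray = observed - self.label_universe
        if stray:
            raise ValueError(f"bin labels outside label universe: {sorted(stray)}")

    def bins_by_zotu(self) -> dict[str, list[GenomeBin]]:
        grouped: dict[str, list[GenomeBin]] = {}
        unassigned = 0
        for b in self.bins:
            if b.zotu is None:
                unassigned += 1
                continue
            grouped.setdefault(b.zotu, []).append(b)
        if unassigned:
            logger.info("excluded %d bins without a ZOTU assignment", unassigned)
        return grouped


def occupancy_by_zotu(
    catalog: GenomeCatalog, labels: Iterable[str] | None = None
) -> pd.DataFrame:
    """Fraction of each ZOTU's genomes possessing each gene label.

    Presence is binary (>=1 copy); copy number is reported separately in
    ``n_copies`` but does not affect the fraction.  Bins without a ZOTU are
    excluded (logged).
    """
    labels = sorted(labels) if labels is not None else sorted(catalog.label_universe)
    rows = []
    for zotu, bins in sorted(catalog.bins_by_zotu().items()):
        for label in labels:
            n_with = sum(1 for b in bins if b.has_label(label))
            rows.append(
                {
                    "zotu": zotu,
                    "label": label,
                    "n_genomes": len(bins),
                    "n_with_label": n_with,
                    "n_copies": sum(b.gene_labels.get(label, 0) for b in bins),
                    "fraction": n_with / len(bins),
                }
            )
    return pd.DataFrame(
        rows, columns=["zotu", "label", "n_genomes", "n_with_label", "n_copies", "fraction"]
    )


def cooccurrence_fraction(
    catalog: GenomeCatalog, label_a: str, label_b: str
) -> tuple[int, float]:
    """Among genomes possessing ``label_a``, the fraction also possessing
    ``label_b``.  Returns ``(n_with_a, fraction)``; NaN when none carry A."""
    for label in (label_a, label_b):
        if label not in catalog.label_universe:
            raise ValueError(f"label {label!r} not in catalog label universe")
    with_a = [b for b in catalog.bins if b.has_label(label_a)]
    if not with_a:
        return 0, float("nan")
    n_both = sum(1 for b in with_a if b.has_label(label_b))
    return len(with_a), n_both / len(with_a)


@dataclass(frozen=True)
class ModuleCall:
    present: bool
    satisfied_by: frozenset[str]


def pathway_completeness_bin(
    catalog: GenomeCatalog, bin_id: str, modules: Iterable[str] | None = None
) -> dict[str, ModuleCall]:
    """Which pathway modules a single genome bin satisfies, and by which genes."""
    by_id = {b.bin_id: b for b in catalog.bins}
    if bin_id not in by_id:
        raise ValueError(f"unknown bin {bin_id!r}")
    return _module_calls(catalog, by_id[bin_id], modules)


def pathway_completeness_zotu(
    catalog: GenomeCatalog, zotu: str, modules: Iterable[str] | None = None
) -> tuple[dict[str, ModuleCall], dict[str, dict[str, ModuleCall]]]:
    """ZOTU-level module presence (majority vote) plus per-genome calls.

    A module is present at the ZOTU level when at least half of the ZOTU's
    genomes possess it — deliberately distinct from "any genome", since
    incomplete bins produce false-negative per-genome calls.
    """
    grouped = catalog.bins_by_zotu()
    if zotu not in grouped:
        raise ValueError(f"unknown ZOTU {zotu!r}")
    per_genome = {b.bin_id: _module_calls(catalog, b, modules) for b in grouped[zotu]}
    module_names = _resolve_modules(catalog, modules)
    zotu_call = {}
    for module in module_names:
        votes = [calls[module].present for calls in per_genome.values()]
        satisfied = frozenset().union(
            *(calls[module].satisfied_by for calls in per_genome.values())
        )
        present = sum(votes) / len(votes) >= MAJORITY_FRACTION
        zotu_call[module] = ModuleCall(present, satisfied if present else frozenset())
    return zotu_call, per_genome


def _resolve_modules(catalog: GenomeCatalog, modules: Iterable[str] | None) -> list[str]:
    if modules is None:
        return list(catalog.pathway_model)
    modules = list(modules)
    unknown = [m for m in modules if m not in catalog.pathway_model]
    if unknown:
        raise ValueError(f"unknown pathway modules: {unknown}")
    return modules


def _module_calls(
    catalog: GenomeCatalog, genome: GenomeBin, modules: Iterable[str] | None
) -> dict[str, ModuleCall]:
    calls = {}
    for module in _resolve_modules(catalog, modules):
        hits = frozenset(
            l for l in catalog.pathway_model[module] if genome.has_label(l)
        )
        calls[module] = ModuleCall(bool(hits), hits)
    return calls


def module_completeness_table(catalog: GenomeCatalog) -> pd.DataFrame:
    """Tidy per-genome and per-ZOTU module presence (for the report stage)."""
    rows = []
    for zotu, _bins in sorted(catalog.bins_by_zotu().items()):
        zotu_call, per_genome = pathway_completeness_zotu(catalog, zotu)
        for module, call in zotu_call.items():
            rows.append(
                {
                    "level": "zotu",
                    "id": zotu,
                    "zotu": zotu,
                    "module": module,
                    "present": call.present,
                    "satisfied_by": ",".join(sorted(call.satisfied_by)),
                }
            )
        for bin_id, calls in sorted(per_genome.items()):
            for module, call in calls.items():
                rows.append(
                    {
                        "level": "genome",
                        "id": bin_id,
                        "zotu": zotu,
                        "module": module,
                        "present": call.present,
                        "satisfied_by": ",".join(sorted(call.satisfied_by)),
                    }
                )
    return pd.DataFrame(
        rows, columns=["level", "id", "zotu", "module", "present", "satisfied_by"]
    )
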