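"""Derived glycosylation traits computed from the quantitation matrix.

A derived trait aggregates the internal-standard-normalized ratios of all
glycans sharing a structural feature.  Two kinds exist:

* ``sum`` traits: the plain sum of ratios over qualifying glycans
  (e.g. fucosylation = sum over all glycans carrying at least one fucose);
* ``per_antenna`` traits: abundance-weighted degrees such as
  galactosylation per antenna,
  ``sum(galactoses_i * q_i) / sum(antennae_i * q_i)`` over glycans with at
  least one antenna, which is invariant to a global rescaling of the
  ratios.

The default registry holds 18 traits spanning monosaccharide features
(fucosylation, galactosylation, sialylation), structural classes
(high-mannose / hybrid / complex, antennarity) and sialylation linkage and
modification detail (alpha2,3 vs alpha2,6, Neu5Ac vs Neu5Gc, branched
sialic acid, O-acetylation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .glycan_model import (
    GlycanComposition,
    StructuralClass,
    TheoreticalLibrary,
    classify_structure,
    parse_composition,
)
from .quant_qc import QuantTable

logger = logging.getLogger(__name__)

Predicate = Callable[[GlycanComposition, StructuralClass], bool]
Weight = Callable[[GlycanComposition, StructuralClass], float]


@dataclass(frozen=True)
class TraitDefinition:
    """One derived trait: a predicate over composition/structure, and for
    per-antenna traits a numerator and denominator weight function."""

    name: str
    kind: str  # "sum" | "per_antenna"
    predicate: Predicate
    numerator: Weight | None = None
    denominator: Weight | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sum", "per_antenna"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "per_antenna" and (
            self.numerator is None or self.denominator is None
        ):
            raise ValueError("per_antenna traits need weight functions")


def default_registry() -> list[TraitDefinition]:
    """The default 18-trait registry."""
    def sum_trait(name: str, pred: Predicate) -> TraitDefinition:
        return TraitDefinition(name=name, kind="sum", predicate=pred)

    return [
        sum_trait("fucosylation", lambda c, s: c.F >= 1),
        sum_trait("afucosylation", lambda c, s: c.F == 0),
        TraitDefinition(
            name="galactosylation_per_antenna",
            kind="per_antenna",
            predicate=lambda c, s: s.antennae > 0,
            numerator=lambda c, s: s.galactoses,
            denominator=lambda c, s: s.antennae,
        ),
        TraitDefinition(
            name="sialylation_per_antenna",
            kind="per_antenna",
            predicate=lambda c, s: s.antennae > 0,
            numerator=lambda c, s: s.sialic,
            denominator=lambda c, s: s.antennae,
        ),
        sum_trait("high_mannose", lambda c, s: s.label == "high_mannose"),
        sum_trait("hybrid", lambda c, s: s.label == "hybrid"),
        sum_trait("complex", lambda c, s: s.label == "complex"),
        sum_trait("monoantennary", lambda c, s: s.antennae == 1),
        sum_trait("biantennary", lambda c, s: s.antennae == 2),
        sum_trait("triantennary", lambda c, s: s.antennae == 3),
        sum_trait("a23_sialylation", lambda c, s: s.a23 >= 1),
        sum_trait("a26_sialylation", lambda c, s: s.a26 >= 1),
        sum_trait("neu5ac_sialylation", lambda c, s: s.neu5ac >= 1),
        sum_trait("neu5gc_sialylation", lambda c, s: s.neu5gc >= 1),
        sum_trait("branched_sialic", lambda c, s: s.branched),
        sum_trait("oacetylated_sialylation", lambda c, s: c.Ac >= 1),
        sum_trait("sialylation", lambda c, s: s.sialic >= 1),
        sum_trait("asialylation", lambda c, s: s.sialic == 0),
    ]


#: extra trait isolating the CR-elevated class: O-acetylated sialoglycans
#: carrying only alpha2,6-linked sialic acid (no lactonized residues).
#: Not part of the default 18-trait registry; append it when the
#: O-acetylation/linkage interaction is of interest.
OACETYLATED_A26_TRAIT = TraitDefinition(
    name="oacetylated_a26_sialylation",
    kind="sum",
    predicate=lambda c, s: c.Ac >= 1 and s.a23 == 0,
)


def acetylated_glycan_report(quant: QuantTable) -> pd.DataFrame:
    """Per-glycan view of the O-acetylated sialoglycans in the panel.

    Returns the masked ratios of every Ac-carrying glycan, annotated with
    whether it is purely alpha2,6-linked; complements the aggregate
    O-acetylation trait with the individual-glycan split.
    """
    vals = quant.masked_values()
    rows = []
    for g in vals.columns:
        c, s = parse_composition(g), classify_structure(g)
        if c.Ac >= 1:
            rows.append({"glycan": g, "pure_a26": s.a23 == 0})
    return pd.DataFrame(rows)


@dataclass
class TraitTable:
    """Samples x traits matrix with the registry and per-trait provenance."""

    values: pd.DataFrame
    meta: pd.DataFrame
    registry: list[TraitDefinition]
    contributors: dict[str, list[str]]


def compute_traits(
    quant: QuantTable,
    registry: Sequence[TraitDefinition] | None = None,
) -> TraitTable:
    """Evaluate the trait registry on a quantitation table.

    Outlier-masked cells are excluded; a missing contributing glycan simply
    reduces the sums (count logged).  A per-antenna trait whose denominator
    is zero (or whose contributors are all missing) yields a missing value
    for that sample.
    """
    if registry is None:
        registry = default_registry()
    vals = quant.masked_values()
    structures = {
        g: (parse_composition(g), classify_structure(g)) for g in vals.columns
    }

    cols: dict[str, pd.Series] = {}
    contributors: dict[str, list[str]] = {}
    for trait in registry:
        members = [
            g for g, (c, s) in structures.items() if trait.predicate(c, s)
        ]
        contributors[trait.name] = members
        sub = vals[members]
        if trait.kind == "sum":
            cols[trait.name] = sub.sum(axis=1, min_count=0)
        else:
            w_num = np.array(
                [trait.numerator(*structures[g]) for g in members], dtype=float
            )
            w_den = np.array(
                [trait.denominator(*structures[g]) for g in members], dtype=float
            )
            num = (sub * w_num).sum(axis=1, min_count=1)
            den = (sub * w_den).sum(axis=1, min_count=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = num / den
            cols[trait.name] = ratio.where(den > 0)

    values = pd.DataFrame(cols, index=vals.index)
    n_missing = int(vals.isna().to_numpy().sum())
    if n_missing:
        logger.info(
            "trait computation over %d samples with %d missing glycan cells",
            len(vals), n_missing,
        )
    return TraitTable(
        values=values,
        meta=quant.meta.copy(),
        registry=list(registry),
        contributors=contributors,
    )


def export_traits(table: TraitTable, path: str | Path) -> Path:
    """Write the trait table as TSV with a provenance header.

    Header comment lines record each trait's kind and contributing glycans;
    the file reads back with ``pandas.read_csv(..., sep="\\t", comment="#",
    index_col=0)``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# derived glycosylation traits\n")
        for trait in table.registry:
            members = ",".join(table.contributors.get(trait.name, []))
            fh.write(f"# {trait.name}\tkind={trait.kind}\tglycans={members}\n")
        table.values.to_csv(fh, sep="\t", float_format="%.9g")
    return path
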