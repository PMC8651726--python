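"""Classification of lipid-binding effects from multi-condition comparisons.

Three pairwise comparisons — apo vs liposomes without the anionic lipid
(BMP), apo vs liposomes with BMP, and the direct without-vs-with-BMP
comparison — jointly discriminate whether a protected region binds the
anionic lipid specifically, binds zwitterionic lipids regardless of BMP, or
shows BMP-enhanced unspecific binding.  A second layer compares tagged and
untagged constructs to flag effects artificially induced or abolished by an
N-terminal purification tag.  Peptide-level significance calls are
consolidated into maximal residue regions for painting onto structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .stats import ComparisonResult, DifferenceRecord

__all__ = [
    "DIRECTIONS",
    "CATEGORIES",
    "CATEGORY_PRIORITY",
    "LipidEffectCall",
    "RegionAnnotation",
    "peptide_direction",
    "classify_lipid_effect",
    "classify_tag_effect",
    "consolidate_regions",
    "paint_residues",
    "write_bfactor_pdb",
]

DIRECTIONS = ("protection", "deprotection", "none")

CATEGORIES = (
    "bmp_specific",
    "zwitterionic",
    "bmp_enhanced",
    "tag_induced",
    "tag_abolished",
    "destabilized_by_bmp",
    "none",
)

#: Priority used to resolve conflicting categories on overlapping regions.
CATEGORY_PRIORITY = {
    "bmp_specific": 0,
    "bmp_enhanced": 1,
    "zwitterionic": 2,
    "destabilized_by_bmp": 3,
    "tag_induced": 4,
    "tag_abolished": 5,
    "none": 6,
}


@dataclass(frozen=True)
class LipidEffectCall:
    """Category call for one region, with the evidence triple that made it."""

    start: int
    end: int
    category: str
    direction: str
    magnitude: float
    timepoint_of_max: float
    evidence: tuple[str, str, str] = ("none", "none", "none")
    degraded_from_enhanced: bool = False


@dataclass(frozen=True)
class RegionAnnotation:
    """A maximal interval of concordantly significant peptides.

    ``value`` is the maximum absolute difference (RFU units when controls
    were available, Da otherwise) over the region's peptides and timepoints;
    the timepoint where that maximum occurred is recorded because structure
    colouring uses the timepoint showing the highest difference.
    """

    start: int
    end: int
    value: float
    direction: str
    timepoint_of_max: float
    peptides: tuple[tuple[int, int], ...]
    category: str = "none"


def peptide_direction(
    records: list[DifferenceRecord], min_timepoints: int = 1
) -> tuple[str, float, float]:
    """Summarize one peptide's difference records into a directional call.

    Returns (direction, magnitude, timepoint_of_max).  The peptide is called
    significant when at least ``min_timepoints`` timepoints are significant;
    the direction and magnitude come from the timepoint with the largest
    absolute difference (RFU-normalized when available).
    """
    sig = [r for r in records if r.significant]
    if len(sig) < min_timepoints:
        return "none", 0.0, float("nan")
    best = max(sig, key=lambda r: abs(r.delta_rfu if r.delta_rfu is not None else r.delta))
    mag = abs(best.delta_rfu if best.delta_rfu is not None else best.delta)
    return best.sign, mag, best.timepoint


def classify_lipid_effect(
    sig_apo_vs_noBMP: str, sig_apo_vs_BMP: str, sig_noBMP_vs_BMP: str
) -> str:
    """Map an evidence triple of directions onto a lipid-effect category.

    Arguments are the directional calls ("protection" / "deprotection" /
    "none") of the three comparisons, each with the first-listed state as
    reference.  The decision table is total over all 27 triples:

    - no effect without BMP, protection with BMP, direct comparison
      significant -> ``bmp_specific`` (the anionic lipid drives the effect);
    - protection in both liposome states, direct comparison silent ->
      ``zwitterionic`` (the neutral lipids suffice);
    - protection in both and the direct comparison confirms further
      protection with BMP -> ``bmp_enhanced``;
    - no effect without BMP, deprotection with BMP, direct comparison
      significant -> ``destabilized_by_bmp``;
    - every other triple -> ``none``.
    """
    for d in (sig_apo_vs_noBMP, sig_apo_vs_BMP, sig_noBMP_vs_BMP):
        if d not in DIRECTIONS:
            raise ValueError(f"unknown direction {d!r}; expected one of {DIRECTIONS}")
    a, b, c = sig_apo_vs_noBMP, sig_apo_vs_BMP, sig_noBMP_vs_BMP
    if a == "none" and b == "protection" and c != "none":
        return "bmp_specific"
    if a == "protection" and b == "protection":
        if c == "none":
            return "zwitterionic"
        if c == "protection":
            return "bmp_enhanced"
        return "none"
    if a == "none" and b == "deprotection" and c != "none":
        return "destabilized_by_bmp"
    return "none"


def classify_tag_effect(call_untagged: str, call_tagged: str) -> str:
    """Compare a region's category between untagged and tagged constructs."""
    untag = call_untagged != "none"
    tag = call_tagged != "none"
    if untag and tag:
        return "constitutive"
    if tag:
        return "tag_induced"
    if untag:
        return "tag_abolished"
    return "concordant_none"


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def consolidate_regions(
    diff_records: list[DifferenceRecord] | ComparisonResult,
    min_timepoints: int = 1,
) -> list[RegionAnnotation]:
    """Merge significant peptides into maximal regions.

    Peptides significant at at least ``min_timepoints`` timepoints are
    unioned into maximal residue intervals (peptides touching or overlapping
    merge).  A region's painting value is the maximum absolute difference
    over its peptides and timepoints, with the responsible timepoint and
    direction recorded.  Residues covered only by non-significant peptides
    carry no region; residues without any peptide are distinguished later by
    :func:`paint_residues`.
    """
    records = diff_records.records if isinstance(diff_records, ComparisonResult) else diff_records
    by_pep: dict[tuple[int, int], list[DifferenceRecord]] = {}
    for rec in records:
        by_pep.setdefault((rec.peptide.start, rec.peptide.end), []).append(rec)

    calls: dict[tuple[int, int], tuple[str, float, float]] = {}
    for key, recs in by_pep.items():
        direction, mag, tp = peptide_direction(recs, min_timepoints)
        if direction != "none":
            calls[key] = (direction, mag, tp)
    if not calls:
        return []

    regions: list[RegionAnnotation] = []
    for start, end in _merge_intervals(list(calls)):
        members = [k for k in calls if start <= k[0] and k[1] <= end]
        best_key = max(members, key=lambda k: calls[k][1])
        direction, mag, tp = calls[best_key]
        directions = {calls[k][0] for k in members}
        if len(directions) > 1:
            warnings.warn(
                f"region {start}-{end} merges peptides with discordant "
                f"directions {sorted(directions)}; keeping the largest effect",
                stacklevel=2,
            )
        regions.append(
            RegionAnnotation(start, end, mag, direction, tp, tuple(sorted(members)))
        )
    return regions


def paint_residues(
    regions: list[RegionAnnotation],
    protein_length: int,
    covered_residues: set[int] | None = None,
) -> pd.DataFrame:
    """Per-residue attribute table for structure painting.

    One row per residue with the region value, category, direction and a
    data status: residues outside every peptide are ``no_data`` (grey in a
    structure rendering); covered residues without a significant region are
    ``data`` with value 0.  Overlapping regions with conflicting categories
    resolve by priority (BMP-specific over BMP-enhanced over zwitterionic
    over the rest); ties within a priority keep the larger value.  Where a
    shorter region is nested inside a longer one it wins for its own
    residues, localizing the effect.
    """
    for reg in regions:
        if reg.start < 1 or reg.end > protein_length:
            raise ValueError(f"region {reg.start}-{reg.end} outside protein bounds")
    if covered_residues is None:
        covered_residues = set(range(1, protein_length + 1))

    value = [0.0] * (protein_length + 1)
    category = ["none"] * (protein_length + 1)
    direction = ["none"] * (protein_length + 1)
    owner: list[tuple[int, int] | None] = [None] * (protein_length + 1)

    # Longer regions first so fully nested shorter regions overwrite
    # (sub-peptide localization).
    for reg in sorted(regions, key=lambda r: -(r.end - r.start)):
        for i in range(reg.start, reg.end + 1):
            prev = owner[i]
            if prev is None:
                take = True
            elif reg.start >= prev[0] and reg.end <= prev[1]:
                take = True  # nested: the more local call wins its residues
            elif reg.category != category[i]:
                prio_new = CATEGORY_PRIORITY.get(reg.category, 6)
                prio_old = CATEGORY_PRIORITY.get(category[i], 6)
                take = prio_new < prio_old
                warnings.warn(
                    f"residue {i}: conflicting categories "
                    f"{category[i]!r} vs {reg.category!r}; keeping higher priority",
                    stacklevel=2,
                )
            else:
                take = reg.value > value[i]
            if take:
                value[i] = reg.value
                category[i] = reg.category
                direction[i] = reg.direction
                owner[i] = (reg.start, reg.end)

    rows = []
    for i in range(1, protein_length + 1):
        status = "data" if i in covered_residues else "no_data"
        rows.append(
            {
                "residue": i,
                "value": value[i] if status == "data" else 0.0,
                "category": category[i] if status == "data" else "none",
                "direction": direction[i] if status == "data" else "none",
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def write_bfactor_pdb(pdb_in: str, attributes: pd.DataFrame, pdb_out: str) -> None:
    """Copy a PDB file with per-residue values written into the B-factor column.

    Coordinates pass through untouched; residues absent from ``attributes``
    (or without data) get B-factor 0.  Values are scaled by 100 so RFU
    differences land in a readable 0-100 range.
    """
    import gemmi

    values = {
        int(row.residue): float(row.value) * 100.0
        for row in attributes.itertuples(index=False)
        if row.status == "data"
    }
    structure = gemmi.read_pdb(pdb_in)
    for model in structure:
        for chain in model:
            for residue in chain:
                b = values.get(residue.seqid.num, 0.0)
                for atom in residue:
                    atom.b_iso = b
    structure.write_pdb(pdb_out)
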