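"""Dataset filtering rules and the compound-centric dataset builder.

``filter_censored`` removes floor-censored records (Davis-style pKd = 5
artifacts).  ``filter_uninformative`` drops every bioactivity of a compound
or target whose activity profile a model could memorize rather than learn:
one-sided around the activity threshold, extreme active/inactive ratio, or
near-constant values.  ``build_compound_centric`` assembles the small-scale
classification datasets around a center compound, and ``augment_negatives``
balances them with similarity-constrained negative proteins.
"""

from __future__ import annotations

import json
import math
import random as _random
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from dtibench.compounds import tanimoto
from dtibench.errors import InputError
from dtibench.io import BioactivityTable, FeatureTable


@dataclass
class FilterReport:
    """Which records were removed and why; each removal is attributed to the
    first rule that fired (censored -> one-sided -> ratio -> low-sd)."""

    removed_censored: List[int] = field(default_factory=list)
    removed_by_rule: Dict[str, Dict[str, List]] = field(default_factory=dict)
    threshold_used: Optional[float] = None

    def removed_record_ids(self) -> Set[int]:
        out = set(self.removed_censored)
        for rule in self.removed_by_rule.values():
            out.update(rule.get("record_ids", []))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "removed_censored": sorted(self.removed_censored),
                "removed_by_rule": {
                    k: {"entities": sorted(v["entities"]),
                        "record_ids": sorted(v["record_ids"])}
                    for k, v in self.removed_by_rule.items()
                },
                "threshold_used": self.threshold_used,
            },
            indent=2,
        )


def filter_censored(
    table: BioactivityTable, floor: float = 5.0
) -> Tuple[BioactivityTable, FilterReport]:
    """Drop records whose activity equals the censoring floor exactly
    (tolerance 1e-9); these encode 'no activity at the maximum dose', not a
    real affinity."""
    removed = [r.record_id for r in table if abs(r.activity - floor) <= 1e-9]
    kept = [r.record_id for r in table if abs(r.activity - floor) > 1e-9]
    report = FilterReport(removed_censored=removed, threshold_used=floor)
    return table.subset(kept), report


def _entity_flags(
    activities: Sequence[float], threshold: float, ratio_cap: float, min_sd: float
) -> Optional[str]:
    """First-firing memorization rule for one entity's activity list, or None.

    (a) one-sided: all active or all inactive at the threshold (active means
        activity > threshold);
    (b) active:inactive ratio > ratio_cap or < 1/ratio_cap;
    (c) sample standard deviation < min_sd.
    """
    n_active = sum(1 for a in activities if a > threshold)
    n_inactive = len(activities) - n_active
    if n_active == 0 or n_inactive == 0:
        return "one_sided"
    ratio = n_active / n_inactive
    if ratio > ratio_cap or ratio < 1.0 / ratio_cap:
        return "ratio"
    if len(activities) >= 2 and statistics.stdev(activities) < min_sd:
        return "low_sd"
    return None


def filter_uninformative(
    train_table: BioactivityTable,
    threshold: Union[float, str] = "median",
    ratio_cap: float = 4.0,
    min_sd: float = 0.3,
) -> Tuple[BioactivityTable, FilterReport]:
    """Remove all bioactivities of memorizable compounds and targets.

    Each pass evaluates every compound and every target against the three
    rules and removes the union of flagged entities' records; passes repeat
    until no entity is flagged, so the returned table actually satisfies the
    rules and the filter is idempotent.  ``threshold='median'`` resolves to
    the median activity of the input table, once, before filtering.
    """
    if len(train_table) == 0:
        raise InputError("cannot filter an empty table")
    thr = (
        float(np.median(train_table.activities()))
        if threshold == "median"
        else float(threshold)
    )
    report = FilterReport(threshold_used=thr)
    for rule in ("one_sided", "ratio", "low_sd"):
        report.removed_by_rule[rule] = {"entities": [], "record_ids": []}

    kept: Set[int] = {r.record_id for r in train_table}
    flagged_entities: Set[str] = set()
    changed = True
    while changed and kept:
        changed = False
        # evaluate every entity against the same snapshot, then remove
        round_flags = []
        for index, prefix in ((train_table.compound_index, "compound:"),
                              (train_table.protein_index, "target:")):
            for entity_id, rids in index.items():
                live = [r for r in rids if r in kept]
                if not live or prefix + entity_id in flagged_entities:
                    continue
                acts = [train_table[r].activity for r in live]
                rule = _entity_flags(acts, thr, ratio_cap, min_sd)
                if rule is not None:
                    round_flags.append((prefix + entity_id, rule, live))
        for name, rule, live in round_flags:
            flagged_entities.add(name)
            report.removed_by_rule[rule]["entities"].append(name)
            report.removed_by_rule[rule]["record_ids"].extend(
                r for r in live if r in kept
            )
            kept.difference_update(live)
            changed = True
    # attribute each record to its first-firing rule only
    seen: Set[int] = set()
    for rule in ("one_sided", "ratio", "low_sd"):
        ids = report.removed_by_rule[rule]["record_ids"]
        deduped = [r for r in ids if r not in seen]
        seen.update(deduped)
        report.removed_by_rule[rule]["record_ids"] = deduped

    return train_table.subset(sorted(kept)), report


@dataclass
class CompoundCentricDataset:
    """Targets of one compound cluster, labelled active/inactive."""

    center_id: str
    member_ids: List[str]
    positives: Set[str]
    negatives: Set[str]

    def __post_init__(self):
        if self.positives & self.negatives:
            raise InputError("positives and negatives overlap")


def build_compound_centric(
    center: str,
    compounds: FeatureTable,
    table: BioactivityTable,
    member_threshold: float = 0.3,
    active_cutoff: float = 5.0,
) -> CompoundCentricDataset:
    """Cluster compounds around a center (Tanimoto >= member_threshold),
    pool the cluster's bioactivities per protein (median aggregation), and
    label proteins active when the aggregate exceeds ``active_cutoff``."""
    if center not in compounds:
        raise InputError(f"center compound {center!r} not in the feature table")
    center_fp = compounds[center]
    members = sorted(
        cid for cid in compounds.ids if tanimoto(center_fp, compounds[cid]) >= member_threshold
    )
    member_set = set(members)
    per_protein: Dict[str, List[float]] = {}
    for rec in table:
        if rec.compound_id in member_set:
            per_protein.setdefault(rec.protein_id, []).append(rec.activity)
    positives = {p for p, acts in per_protein.items() if statistics.median(acts) > active_cutoff}
    negatives = set(per_protein) - positives
    return CompoundCentricDataset(center, members, positives, negatives)


def augment_negatives(
    dataset: CompoundCentricDataset,
    protein_sim: Mapping[str, Mapping[str, float]],
    candidates: Sequence[str],
    pos_max: float = 0.50,
    neg_max: float = 0.80,
    seed: int = 0,
) -> CompoundCentricDataset:
    """Add candidate proteins to the negatives until classes balance.

    Similarities are percent identity expressed as fractions in [0,1] (or
    [0,100]; both accepted, values > 1 are scaled down).  A candidate is
    eligible when its maximum similarity to current positives is below
    ``pos_max`` and to current negatives — including negatives added earlier
    in this call — is below ``neg_max``.  Candidate order is a seeded
    shuffle; best effort with a warning when balance cannot be reached.
    """
    def sim(a: str, b: str) -> float:
        v = protein_sim.get(a, {}).get(b)
        if v is None:
            v = protein_sim.get(b, {}).get(a, 0.0)
        v = float(v)
        return v / 100.0 if v > 1.0 else v

    positives = set(dataset.positives)
    negatives = set(dataset.negatives)
    order = [c for c in candidates if c not in positives and c not in negatives]
    _random.Random(seed).shuffle(order)
    for cand in order:
        if len(negatives) >= len(positives):
            break
        max_pos = max((sim(cand, p) for p in positives), default=0.0)
        max_neg = max((sim(cand, n) for n in negatives), default=0.0)
        if max_pos < pos_max and max_neg < neg_max:
            negatives.add(cand)
    if len(negatives) < len(positives):
        warnings.warn(
            f"could not balance classes: {len(positives)} positives vs "
            f"{len(negatives)} negatives after augmentation",
            stacklevel=2,
        )
    return CompoundCentricDataset(
        dataset.center_id, dataset.member_ids, positives, negatives
    )
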