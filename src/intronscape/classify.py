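"""Rule-based intron classification: canonical / BOC1 / introner-element (IE).

BOC1 introns are short (<75 nt), AT-rich (<43 GC%) introns lying inside a
configured low-GC chromosomal region; IE membership comes from de novo
repeat-family discovery and takes precedence; everything else is canonical.
Both thresholds are strict, so boundary cases (length exactly 75, GC exactly
43) fall to canonical.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .features import find_branch_point, splice_sites
from .model import AnnotationSet, Intron


@dataclass
class ClassifierConfig:
    boc1_max_len: int = 75  # strict <
    boc1_max_gc: float = 43.0  # strict <
    # seq_id -> list of 0-based half-open intervals
    boc1_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    ie_precedence: bool = True

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ClassifierConfig":
        """Load config; region intervals in the file are 1-based inclusive."""
        with open(path) as fh:
            raw = json.load(fh)
        regions = {
            sid: [(int(s) - 1, int(e)) for s, e in ivals]
            for sid, ivals in raw.get("boc1_regions", {}).items()
        }
        return cls(
            boc1_max_len=int(raw.get("boc1_max_len", 75)),
            boc1_max_gc=float(raw.get("boc1_max_gc", 43.0)),
            boc1_regions=regions,
            ie_precedence=bool(raw.get("ie_precedence", True)),
        )

    def to_json(self, path: str | os.PathLike) -> None:
        raw = {
            "boc1_max_len": self.boc1_max_len,
            "boc1_max_gc": self.boc1_max_gc,
            "boc1_regions": {
                sid: [[s + 1, e] for s, e in ivals] for sid, ivals in self.boc1_regions.items()
            },
            "ie_precedence": self.ie_precedence,
        }
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=1)


def in_boc1_region(intron: Intron, cfg: ClassifierConfig) -> bool:
    """True iff the intron lies entirely within a configured region."""
    for s, e in cfg.boc1_regions.get(intron.seq_id, ()):
        if s <= intron.start and intron.end <= e:
            return True
    return False


def classify_intron(intron: Intron, is_ie_member: bool, cfg: ClassifierConfig,
                    family_id: Optional[str] = None) -> str:
    """Class label for one intron given its (already decided) IE membership."""
    if is_ie_member and cfg.ie_precedence:
        return f"ie:{family_id}" if family_id else "ie"
    if (
        intron.length < cfg.boc1_max_len
        and intron.gc_percent < cfg.boc1_max_gc
        and in_boc1_region(intron, cfg)
    ):
        return "boc1"
    if is_ie_member:  # ie_precedence off: geography first, evidence second
        return f"ie:{family_id}" if family_id else "ie"
    return "canonical"


def classify_all(
    a: AnnotationSet,
    family_membership: Mapping[str, str] | None,
    cfg: ClassifierConfig,
) -> AnnotationSet:
    """Label every intron in place. ``family_membership`` maps intron id -> family id."""
    family_membership = family_membership or {}
    for i in a.introns:
        fam = family_membership.get(i.id)
        i.class_label = classify_intron(i, fam is not None, cfg, fam)
        i.family_id = fam
    return a


def _base_class(label: str) -> str:
    return "ie" if label.startswith("ie") else label


def summarize_classes(
    a: AnnotationSet,
    branch_motif: str = "NCTGAC",
    branch_window: tuple[int, int] = (43, 52),
    by_family: bool = False,
) -> pd.DataFrame:
    """Per-class property summary (counts, lengths, GC, splice sites, phase,
    branch-point hit rate) plus a totals row.

    With ``by_family`` IE families are reported as separate rows, otherwise
    all IE introns collapse into one "ie" row.
    """
    groups: dict[str, list[Intron]] = {}
    for i in a.introns:
        key = i.class_label if by_family else _base_class(i.class_label)
        groups.setdefault(key, []).append(i)
    rows = []
    def _row(name: str, members: Iterable[Intron]) -> dict:
        members = list(members)
        n = len(members)
        lengths = [m.length for m in members]
        gcs = [m.gc_percent for m in members]
        phases = [0, 0, 0]
        donors: dict[str, int] = {}
        acceptors: dict[str, int] = {}
        bp = 0
        for m in members:
            phases[m.phase] += 1
            ss = splice_sites(m)
            donors[ss["donor_status"]] = donors.get(ss["donor_status"], 0) + 1
            acceptors[ss["acceptor_status"]] = acceptors.get(ss["acceptor_status"], 0) + 1
            if find_branch_point(m, branch_motif, branch_window):
                bp += 1
        return {
            "class": name,
            "count": n,
            "mean_length": float(pd.Series(lengths).mean()) if n else float("nan"),
            "median_length": float(pd.Series(lengths).median()) if n else float("nan"),
            "mean_gc": float(pd.Series(gcs).mean()) if n else float("nan"),
            "donor_composition": ";".join(f"{k}={v}" for k, v in sorted(donors.items())),
            "acceptor_composition": ";".join(f"{k}={v}" for k, v in sorted(acceptors.items())),
            "phase0": phases[0],
            "phase1": phases[1],
            "phase2": phases[2],
            "branch_point_rate": bp / n if n else float("nan"),
        }
    for name in sorted(groups):
        rows.append(_row(name, groups[name]))
    rows.append(_row("total", a.introns))
    return pd.DataFrame(rows)
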