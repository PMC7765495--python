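"""Consensus candidate calling: p gate + positive-control-anchored |LFC|
gate per detector, then a >=k-of-n tool vote, with overlap summaries.

The |LFC| threshold can be calibrated from a well-established target gene
of the inhibited pathway (the positive control): the adopted rule takes the
control's |LFC| at its earliest timepoint above a small noise floor and
rounds it down to one decimal. Applied to a control responding (0.58, 1.24,
1.54) over 3/6/9 h this yields 0.5; a control first responding at 0.74
yields 0.7. The rule is an explicit, auditable interpretation of anchoring
a threshold "based on" a known target; ``rule="min_significant"`` and
manual thresholds are available alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .preprocess import ValidationError

__all__ = [
    "ConsensusConfig",
    "calibrate_lfc_threshold",
    "apply_gates",
    "vote",
    "overlap_summary",
]


@dataclass
class ConsensusConfig:
    """Gates for one experiment: p threshold ``alpha``, |LFC| threshold
    ``lam`` and the minimum number of supporting detectors."""

    alpha: float = 0.05
    lam: float = 0.5
    k_min_tools: int = 3
    control_gene: str | None = None
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValidationError("alpha must be in (0,1]")
        if self.lam < 0:
            raise ValidationError("lam must be >= 0")
        if not (1 <= self.k_min_tools <= 4):
            raise ValidationError("k_min_tools must be in 1..4")


def calibrate_lfc_threshold(lfc_table: pd.DataFrame, control_gene: str,
                            noise_floor: float = 0.1,
                            rule: str = "earliest") -> tuple[float, str]:
    """Anchor the |LFC| gate on a positive-control gene.

    ``earliest``: |LFC| at the control's earliest timepoint with
    |LFC| > ``noise_floor``, rounded down to one decimal.
    ``min_significant``: minimum |LFC| over all supra-floor timepoints,
    rounded down likewise.

    Returns (threshold, provenance note).
    """
    if control_gene not in lfc_table.index:
        raise ValidationError(f"control gene {control_gene!r} absent from LFC table; set lam manually")
    prof = lfc_table.loc[control_gene].abs()
    supra = prof[prof > noise_floor]
    if supra.empty or prof.max() < noise_floor:
        raise ValidationError(
            f"control gene {control_gene!r} is flat (max |LFC| {prof.max():.3g}); set lam manually")
    if rule == "earliest":
        anchor_t = supra.index[0]
        val = float(supra.iloc[0])
    elif rule == "min_significant":
        anchor_t = supra.idxmin()
        val = float(supra.min())
    else:
        raise ValidationError(f"unknown anchoring rule {rule!r}")
    lam = math.floor(val * 10.0 + 1e-9) / 10.0
    note = (f"lam={lam} anchored on {control_gene} |LFC|={val:.3g} at {anchor_t} h "
            f"(rule={rule}, floor>{noise_floor})")
    return lam, note


def apply_gates(results: dict[str, pd.DataFrame], lfc_table: pd.DataFrame,
                config: ConsensusConfig) -> dict[str, set]:
    """Per-detector candidate sets: gate p < alpha AND max_t |LFC| >= lam."""
    universes = {name: set(tab.index) for name, tab in results.items()}
    ref = set(lfc_table.index)
    for name, uni in universes.items():
        if uni != ref:
            diff = sorted(uni.symmetric_difference(ref))
            raise ValidationError(f"gene universe mismatch for {name}: {diff[:10]}")
    max_lfc = lfc_table.abs().max(axis=1)
    lfc_pass = set(max_lfc.index[max_lfc >= config.lam])
    out = {}
    col = "p_adj" if config.use_adjusted else "p_raw"
    for name, tab in results.items():
        out[name] = set(tab.index[tab[col] < config.alpha]) & lfc_pass
    return out


def vote(candidate_sets: dict[str, set], k_min_tools: int,
         lfc_table: pd.DataFrame | None = None, lam: float = 0.0) -> pd.DataFrame:
    """>=k-of-n tool vote over per-detector candidate sets.

    Returns consensus calls sorted by (n_tools desc, max_abs_lfc desc,
    gene_id asc); temporal annotation columns are filled when an LFC table
    is supplied.
    """
    if not 1 <= k_min_tools:
        raise ValidationError("k_min_tools must be >= 1")
    if k_min_tools > len(candidate_sets):
        raise ValidationError(
            f"k_min_tools={k_min_tools} exceeds the {len(candidate_sets)} provided tools")
    support: dict[str, list[str]] = {}
    for name in sorted(candidate_sets):
        for g in candidate_sets[name]:
            support.setdefault(g, []).append(name)
    rows = []
    for g, tools in support.items():
        if len(tools) < k_min_tools:
            continue
        row = {"gene_id": g, "n_tools": len(tools), "supporting_tools": ";".join(sorted(tools))}
        if lfc_table is not None and g in lfc_table.index:
            prof = lfc_table.loc[g]
            row["max_abs_lfc"] = float(prof.abs().max())
            first = None
            for t in prof.index:
                v = prof[t]
                row[f"direction_{t}h"] = "up" if (abs(v) >= lam and v > 0) else (
                    "down" if (abs(v) >= lam and v < 0) else "none")
                if first is None and abs(v) >= lam:
                    first = int(t)
            row["first_de_timepoint"] = first if first is not None else pd.NA
        else:
            row["max_abs_lfc"] = np.nan
        rows.append(row)
    cols = ["gene_id", "n_tools", "supporting_tools", "max_abs_lfc"]
    if lfc_table is not None:
        cols += ["first_de_timepoint"] + [f"direction_{t}h" for t in lfc_table.columns]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    df = df.sort_values(["n_tools", "max_abs_lfc", "gene_id"],
                        ascending=[False, False, True], kind="mergesort")
    return df.reindex(columns=[c for c in cols if c in df.columns]).reset_index(drop=True)


def overlap_summary(candidate_sets: dict[str, set]) -> pd.DataFrame:
    """Counts of every tool-combination region (2^n - 1 rows).

    A gene is counted in the region of exactly the tools that called it;
    region counts therefore sum to the size of the union.
    """
    names = sorted(candidate_sets)
    if len(names) > 4:
        raise ValidationError("at most 4 sets supported")
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(candidate_sets[n] for n in combo)) if combo else set()
            outside = set.union(set(), *(candidate_sets[n] for n in names if n not in combo))
            rows.append({"tools": "&".join(combo), "n_tools": r,
                         "count": len(inside - outside)})
    return pd.DataFrame(rows, columns=["tools", "n_tools", "count"])
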