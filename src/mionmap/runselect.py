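"""Jackknife run selection: keep runs that contribute positively to a contrast.

For each subject, the whole-brain maximum t of the contrast is computed from
all runs (T_all) and from every leave-one-run-out subset (T_minus_r).  A run
whose removal *lowers* the maximum (T_minus_r < T_all, strictly) contributed
positively and is kept; ties and increases drop the run.  No topographical
constraint is imposed: the maximum is taken over the configured whole-brain
mask.  The procedure is a single pass and deterministic, and performs
exactly n + 1 subject-level combinations for n runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import firstlevel
from .firstlevel import ContrastMap

logger = logging.getLogger(__name__)

__all__ = ["JackknifeReport", "subject_max_t", "jackknife_select", "apply_selection"]


def subject_max_t(run_maps: list[ContrastMap], mask: np.ndarray) -> float:
    """Whole-brain maximum t of the inverse-variance run combination."""
    if not run_maps:
        raise ValueError("run subset is empty")
    combined = firstlevel.combine_runs(run_maps)
    vals = combined.t[mask.astype(bool)]
    if not np.any(np.isfinite(vals)):
        raise ValueError("no finite t values inside the mask")
    return float(np.nanmax(vals))


@dataclass
class JackknifeReport:
    """Per-run contribution deltas and keep/drop decisions for one subject."""

    subject_id: str
    contrast: str
    t_all: float
    table: pd.DataFrame  # run_id, t_minus, delta, keep

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["keep"], "run_id"])

    def to_tsv(self, path) -> None:
        self.table.assign(subject_id=self.subject_id, t_all=self.t_all).to_csv(
            path, sep="\t", index=False
        )


def jackknife_select(
    run_maps: dict[str, ContrastMap],
    mask: np.ndarray,
    subject_id: str = "",
    contrast: str = "",
) -> JackknifeReport:
    """Leave-one-run-out contribution screening for one subject.

    With a single run the run is kept (with a warning); selection needs at
    least two runs to be informative.
    """
    run_ids = list(run_maps)
    if not run_ids:
        raise ValueError("no runs provided")
    for rid, m in run_maps.items():
        if m is None:
            raise ValueError(f"contrast unavailable for run {rid!r}")
    if len(run_ids) == 1:
        logger.warning(
            "subject %s has a single run; jackknife is uninformative, keeping it",
            subject_id,
        )
        t_all = subject_max_t([run_maps[run_ids[0]]], mask)
        table = pd.DataFrame(
            [{"run_id": run_ids[0], "t_minus": np.nan, "delta": np.nan, "keep": True}]
        )
        return JackknifeReport(subject_id, contrast, t_all, table)

    t_all = subject_max_t([run_maps[r] for r in run_ids], mask)
    rows = []
    for rid in run_ids:
        others = [run_maps[r] for r in run_ids if r != rid]
        t_minus = subject_max_t(others, mask)
        rows.append(
            {
                "run_id": rid,
                "t_minus": t_minus,
                "delta": t_all - t_minus,
                "keep": bool(t_minus < t_all),  # strict: ties drop the run
            }
        )
    return JackknifeReport(subject_id, contrast, t_all, pd.DataFrame(rows))


def apply_selection(
    manifest: pd.DataFrame, reports: dict[str, JackknifeReport]
) -> tuple[pd.DataFrame, dict]:
    """Filter a cohort manifest down to the positively contributing runs.

    Returns the filtered manifest and a summary (total kept, per-subject
    kept counts and their median).  A subject whose every run was dropped is
    retained with zero runs and logged; downstream group maps skip it.
    """
    subjects = manifest["subject_id"].unique()
    missing = [s for s in subjects if s not in reports]
    if missing:
        raise ValueError(f"no jackknife report for subjects: {missing}")
    keep_rows = []
    per_subject = {}
    for subject in subjects:
        selected = set(reports[subject].selected)
        sub = manifest[manifest["subject_id"] == subject]
        kept = sub[sub["run_id"].isin(selected)]
        per_subject[subject] = int(len(kept))
        if len(kept) == 0:
            logger.warning("subject %s has zero positively contributing runs", subject)
        keep_rows.append(kept)
    filtered = pd.concat(keep_rows, ignore_index=True)
    counts = list(per_subject.values())
    summary = {
        "total_runs_kept": int(sum(counts)),
        "per_subject_kept": per_subject,
        "median_runs_kept": float(np.median(counts)) if counts else 0.0,
    }
    return filtered, summary
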