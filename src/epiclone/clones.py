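"""Clone-level complete-demethylation calls and diversity statistics.

A promoter CGI that was fully methylated in the untreated bulk counts as
completely demethylated in a clone when the clone's block β drops below
0.2 — i.e. both alleles of the founder cell lost their methylation. The
statistics here quantify how many promoters each clone demethylates, how
little the demethylated sets overlap between clones, and how much of the
candidate universe is covered by at least one clone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import BETA_UNMETH
from .simulate import InputError
from .tree import Dendrogram, hierarchical_cluster

logger = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching hand-reported percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DemethCallMatrix:
    """Boolean complete-demethylation calls, baseline blocks × clones."""

    calls: pd.DataFrame
    baseline_sample: str
    missing: pd.DataFrame = field(default=None)  # mask of missing β, same shape

    @property
    def block_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def clone_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_baseline(self) -> int:
        return self.calls.shape[0]


def call_complete_demethylation(
    clone_betas: pd.DataFrame,
    baseline_blocks: list[str],
    baseline_sample: str = "bulk-mock",
    beta_unmeth: float = BETA_UNMETH,
) -> DemethCallMatrix:
    """Call β < 0.2 on baseline fully methylated blocks, per clone.

    Missing β never produces a call; the positions are flagged in the
    ``missing`` mask.
    """
    if not baseline_blocks:
        raise InputError("baseline block list is empty")
    absent = [b for b in baseline_blocks if b not in clone_betas.index]
    if absent:
        raise InputError(f"baseline blocks absent from β matrix: {absent[:5]}")
    sub = clone_betas.loc[baseline_blocks]
    missing = sub.isna()
    calls = (sub < beta_unmeth).fillna(False).astype(bool)
    if missing.to_numpy().any():
        logger.warning("%d missing β values produced no call", int(missing.sum().sum()))
    return DemethCallMatrix(calls=calls, baseline_sample=baseline_sample, missing=missing)


def per_clone_counts(calls: DemethCallMatrix) -> pd.DataFrame:
    """Per-clone count and percentage (1 decimal) of baseline blocks called."""
    if calls.calls.empty:
        raise InputError("call matrix is empty")
    counts = calls.calls.sum(axis=0).astype(int)
    pct = counts.map(lambda c: round_half_up(100.0 * c / calls.n_baseline))
    return pd.DataFrame({"count": counts, "percent": pct})


@dataclass
class CloneOverlapMatrix:
    """Directional overlap percentages between clones' demethylated sets.

    entry(A, B) = 100 × |calls_A ∩ calls_B| / |calls_A|; a clone with no
    calls has a missing row. The symmetric Jaccard variant is available as
    an alternative denominator convention.
    """

    directional: pd.DataFrame
    jaccard: pd.DataFrame

    def offdiag_range(self, kind: str = "directional") -> tuple[float, float]:
        mat = self.directional if kind == "directional" else self.jaccard
        vals = mat.where(~np.eye(len(mat), dtype=bool)).to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise InputError("no off-diagonal overlap values")
        return float(vals.min()), float(vals.max())


def pairwise_overlap(calls: DemethCallMatrix) -> CloneOverlapMatrix:
    """All-pairs overlap of per-clone demethylated block sets."""
    if len(calls.clone_ids) < 2:
        raise InputError("need at least 2 clones for overlap")
    sets = {c: set(calls.calls.index[calls.calls[c]]) for c in calls.clone_ids}
    ids = calls.clone_ids
    directional = pd.DataFrame(np.nan, index=ids, columns=ids)
    jaccard = pd.DataFrame(np.nan, index=ids, columns=ids)
    for a in ids:
        if not sets[a]:
            warnings.warn(f"clone {a} has zero calls; overlap row undefined", stacklevel=2)
            continue
        for b in ids:
            inter = len(sets[a] & sets[b])
            directional.loc[a, b] = round_half_up(100.0 * inter / len(sets[a]))
            union = len(sets[a] | sets[b])
            if union:
                jaccard.loc[a, b] = round_half_up(100.0 * inter / union)
    return CloneOverlapMatrix(directional=directional, jaccard=jaccard)


def union_coverage(calls: DemethCallMatrix) -> dict:
    """Count/percentage of baseline blocks demethylated in ≥ 1 clone."""
    if calls.calls.empty:
        raise InputError("call matrix is empty")
    count = int(calls.calls.any(axis=1).sum())
    return {
        "count": count,
        "total": calls.n_baseline,
        "percent": round_half_up(100.0 * count / calls.n_baseline),
    }


def mean_delta_beta(sample: pd.Series, reference: pd.Series) -> float:
    """Mean of (β_reference − β_sample) over shared non-missing blocks,
    in percentage points.

    Applied to a treated sample against the mock baseline this measures
    genome-wide demethylation; the difference between two samples' values
    (e.g. dead pool minus surviving cells) is the demethylation contrast.
    """
    shared = sample.index.intersection(reference.index)
    if shared.empty:
        raise InputError("no shared blocks between sample and reference")
    diff = (reference.loc[shared] - sample.loc[shared]).dropna()
    if diff.empty:
        raise InputError("no non-missing paired blocks")
    return float(diff.mean() * 100.0)


def cluster_clone_profiles(profiles: pd.DataFrame) -> Dendrogram:
    """Hierarchically cluster clones (columns) by their β or call profiles.

    Euclidean distance, complete linkage, lexicographic tie-breaking on
    clone id; constant profiles give a degenerate dendrogram.
    """
    return hierarchical_cluster(profiles.T.astype(float))


# ---------------------------------------------------------------------------
# output writers

def write_calls_tsv(calls: DemethCallMatrix, path: str | Path) -> None:
    calls.calls.astype(int).to_csv(path, sep="\t", index_label="block_id")


def write_overlap_tsv(overlap: CloneOverlapMatrix, path: str | Path) -> None:
    overlap.directional.to_csv(path, sep="\t", index_label="clone", na_rep="NA")


def summarize(calls: DemethCallMatrix) -> dict:
    """Summary of the clone diversity statistics, JSON-serialisable."""
    counts = per_clone_counts(calls)
    overlap = pairwise_overlap(calls) if len(calls.clone_ids) >= 2 else None
    out = {
        "baseline_sample": calls.baseline_sample,
        "n_baseline_blocks": calls.n_baseline,
        "per_clone": {
            c: {"count": int(counts.loc[c, "count"]), "percent": counts.loc[c, "percent"]}
            for c in counts.index
        },
        "min_clone_count": int(counts["count"].min()),
        "max_clone_count": int(counts["count"].max()),
        "union": union_coverage(calls),
    }
    if overlap is not None:
        lo, hi = overlap.offdiag_range("directional")
        out["overlap_directional_range"] = [lo, hi]
        lo, hi = overlap.offdiag_range("jaccard")
        out["overlap_jaccard_range"] = [lo, hi]
    return out
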