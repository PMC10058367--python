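"""Tentacle-vs-mucus label-free quantification and enrichment calls.

The procedure mirrors the quantitative treatment of PEAKS-style exports:

1. Missingness coding: "-" (protein absent from the sample) is MISSING;
   a numeric 0 means detected with low signal.  The two states are kept
   distinct because they are replaced differently.
2. Imputation: MISSING -> 0, then 0 -> floor (default 1e-2).  Cells that
   received the floor keep an "imputed" provenance flag.
3. Normalization: per-sample total-area scaling so every sample sum equals
   the grand mean of sample sums ("none" is available).  The normalization
   method is undefined upstream of this package, so the choice is logged
   into the output provenance.
4. Presence filter: a protein enters the comparison when it is detected
   (non-MISSING and > 0) in at least k of n replicates of either tissue
   (default 2 of 3), evaluated on the RAW table.
5. Group means with mean replacement: per group, the mean is taken over
   observed (non-imputed) cells and every floor-imputed cell in that group
   is replaced by it; a group with no observed cell stays at the floor.
6. Enrichment call: the tissue with the larger group mean; "exclusive"
   is the special case where the other group is entirely imputed.

No significance testing is performed — the comparison is purely
descriptive, by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PipelineConfig, QuantTable, log


@dataclass
class ProteinQuant:
    """Per-feature quantification state after the full procedure."""

    feature_id: str
    raw: dict[tuple[str, int], float]
    final: dict[tuple[str, int], float]
    presence: dict[str, int]
    group_means: dict[str, float]
    enrichment: str  # tentacle | mucus | tie | not_evaluable
    exclusive: bool = False
    n_imputed: int = 0


def impute(q: QuantTable, cfg: PipelineConfig | None = None) -> QuantTable:
    """MISSING -> 0 -> floor, with per-cell provenance flags.

    Idempotent: already-imputed cells (flagged, at the floor) are left
    untouched on a second application.
    """
    if cfg is None:
        cfg = PipelineConfig()
    out = q.copy()
    values = out.values
    missing = values.isna()
    zero = values == 0
    previously = (
        out.imputed
        if out.imputed is not None
        else pd.DataFrame(False, index=values.index, columns=values.columns)
    )
    to_floor = missing | zero
    out.values = values.where(~to_floor, cfg.imputation_floor)
    out.imputed = previously | to_floor
    return out


def normalize(q: QuantTable, method: str = "total_area") -> QuantTable:
    """Scale each sample so its total area equals the grand mean of totals.

    Rank order within a sample is preserved (positive scaling).  A sample
    with zero total area cannot be scaled and is an error.  ``"none"``
    returns the table unchanged.
    """
    if method == "none":
        return q.copy()
    if method != "total_area":
        raise ValueError(f"unknown normalization method {method!r}")
    out = q.copy()
    sums = out.values.sum(axis=0, skipna=True)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise ValueError(f"sample {bad} has zero total area; cannot normalize")
    target = sums.mean()
    factors = target / sums
    out.values = out.values * factors
    for col, f in factors.items():
        log.info("normalization factor %s: %.6g", col, f)
    return out


def presence_filter(
    q: QuantTable, k: int | None = None, n: int | None = None,
    cfg: PipelineConfig | None = None,
) -> list[str]:
    """Feature ids detected in >= k of n replicates of either group.

    Detection means a raw value that is present (non-MISSING) and > 0;
    the filter must therefore run on the raw, pre-imputation table.
    """
    if cfg is None:
        cfg = PipelineConfig()
    k = cfg.presence_k if k is None else k
    n = cfg.presence_n if n is None else n
    if not (0 < k <= n):
        raise ValueError("require 0 < k <= n")
    detected = q.values.notna() & (q.values > 0)
    retained = []
    for fid, row in detected.iterrows():
        if any(row[group].sum() >= k for group in q.groups):
            retained.append(fid)
    return retained


def presence_counts(q: QuantTable) -> pd.DataFrame:
    """Detected-replicate counts per (feature, group) on the raw table."""
    detected = q.values.notna() & (q.values > 0)
    return detected.T.groupby(level="group").sum().T


def group_means_with_replacement(
    q: QuantTable, cfg: PipelineConfig | None = None
) -> dict[str, ProteinQuant]:
    """Group means over observed cells; imputed cells replaced by them.

    ``q`` must be imputed (and typically normalized).  Within each group
    of each feature: the mean is computed over cells that were actually
    observed; every imputed cell is then set to that mean.  A group whose
    cells are all imputed stays at the floor and its mean is the floor
    value.  The recorded group mean equals the post-replacement mean,
    which by construction equals the observed-cell mean when at least one
    cell was observed.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if q.imputed is None:
        raise ValueError("group_means_with_replacement requires an imputed table")
    out: dict[str, ProteinQuant] = {}
    for fid in q.values.index:
        final: dict[tuple[str, int], float] = {}
        means: dict[str, float] = {}
        n_imputed = 0
        exclusive_groups = []
        for group in q.groups:
            vals = q.values.loc[fid, group]
            flags = q.imputed.loc[fid, group]
            observed = vals[~flags]
            if len(observed):
                mean = float(observed.mean())
                for sample, flag in flags.items():
                    final[(group, sample)] = mean if flag else float(vals[sample])
            else:
                mean = float(vals.mean())  # all cells at the floor
                exclusive_groups.append(group)
                for sample in flags.index:
                    final[(group, sample)] = float(vals[sample])
            n_imputed += int(flags.sum())
            means[group] = float(
                np.mean([final[(group, s)] for s in flags.index])
            )
        out[fid] = ProteinQuant(
            feature_id=fid,
            raw={},
            final=final,
            presence={},
            group_means=means,
            enrichment="not_evaluable",
            exclusive=bool(exclusive_groups) and len(exclusive_groups) < len(q.groups),
            n_imputed=n_imputed,
        )
    return out


def enrichment_call(pq: ProteinQuant, rel_tol: float = 1e-9) -> str:
    """Direction of enrichment from the two group means.

    Means equal within ``rel_tol`` (relative) are a tie.  The call is also
    stored on the ProteinQuant.
    """
    mt = pq.group_means.get("tentacle")
    mm = pq.group_means.get("mucus")
    if mt is None or mm is None:
        pq.enrichment = "not_evaluable"
        return pq.enrichment
    scale = max(abs(mt), abs(mm), 1e-300)
    if abs(mt - mm) <= rel_tol * scale:
        pq.enrichment = "tie"
    elif mt > mm:
        pq.enrichment = "tentacle"
    else:
        pq.enrichment = "mucus"
    return pq.enrichment


def run_quant(
    q: QuantTable,
    cfg: PipelineConfig | None = None,
    normalize_method: str = "total_area",
) -> tuple[pd.DataFrame, dict[str, ProteinQuant]]:
    """The full procedure on one table: filter, impute, normalize, call.

    Returns a tidy per-feature frame (presence counts, group means, call)
    restricted to features passing the presence filter, plus the detailed
    per-feature state.
    """
    if cfg is None:
        cfg = PipelineConfig()
    retained = presence_filter(q, cfg=cfg)
    counts = presence_counts(q)
    imputed = impute(q, cfg)
    normalized = normalize(imputed, normalize_method)
    quants = group_means_with_replacement(normalized, cfg)
    rows = []
    for fid in retained:
        pq = quants[fid]
        pq.presence = {g: int(counts.loc[fid, g]) for g in q.groups}
        call = enrichment_call(pq)
        rows.append(
            {
                "feature_id": fid,
                **{f"presence_{g}": pq.presence[g] for g in q.groups},
                **{f"mean_{g}": pq.group_means[g] for g in q.groups},
                "enrichment": call,
                "exclusive": pq.exclusive,
                "n_imputed": pq.n_imputed,
            }
        )
    df = pd.DataFrame(rows)
    log.info(
        "presence filter retained %d of %d features", len(retained), len(q.values)
    )
    return df, {fid: quants[fid] for fid in retained}


def category_composition(
    categories: Mapping[str, Sequence[str]] | pd.Series,
) -> pd.DataFrame:
    """Percentage composition over known features.

    ``categories`` maps feature id -> list of category labels (empty or
    missing = unknown feature, excluded).  A multi-category feature counts
    once per category; the denominator is the number of category
    assignments, so percentages always sum to 100.  Percentages are
    rounded half-up to one decimal.
    """
    if isinstance(categories, pd.Series):
        categories = categories.to_dict()
    tallies: dict[str, int] = {}
    for labels in categories.values():
        if isinstance(labels, str):
            labels = [labels]
        for label in labels or []:
            tallies[label] = tallies.get(label, 0) + 1
    total = sum(tallies.values())
    if total == 0:
        log.warning("no known features; composition table is empty")
        return pd.DataFrame(columns=["category", "count", "percent"])
    rows = []
    for label, count in sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0])):
        pct = Decimal(100 * count / total).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
        rows.append({"category": label, "count": count, "percent": float(pct)})
    return pd.DataFrame(rows)
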