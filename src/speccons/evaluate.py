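"""Cluster-quality statistics for representative spectra.

Multispectral clusters (>= 2 members) with a clear majority peptidoform
(> 50% of the identified members' matches) are the evaluation unit. A
representative whose identification equals the majority peptidoform is a
high-quality representative; one matching a minority member, or no member
at all, is low-quality. Additional summaries: score means stratified by
cluster size, and corroborative/divergent comparison of two methods'
identifications on shared spectra.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    PSM,
    Cluster,
    ClusterQuality,
    MethodComparison,
    Peptidoform,
)

__all__ = [
    "majority_peptidoform",
    "filter_multispectral",
    "classify_representative",
    "quality_ratios",
    "score_by_cluster_size",
    "compare_methods",
    "count_mod_sites",
]

#: Cluster-size strata: singletons through five get their own bin, then
#: half-open-above ranges (5, 10], (10, 20], (20, inf).
SIZE_BINS = ("1", "2", "3", "4", "5", "5-10", "10-20", ">20")


def _form(psm: PSM, sequence_only: bool) -> Peptidoform:
    if sequence_only:
        return Peptidoform(psm.peptide, ())
    return psm.peptidoform


def majority_peptidoform(
    cluster: Cluster,
    member_psms: Mapping[str, PSM],
    sequence_only: bool = False,
) -> tuple[Peptidoform | None, float]:
    """Modal peptidoform among the cluster's identified members.

    Returns ``(form, fraction)`` where the fraction is taken over the
    identified members only. The form is ``None`` when no member is
    identified or when the modal fraction is not strictly greater than 0.5
    (a 50/50 split has no majority).
    """
    forms = [
        _form(member_psms[m], sequence_only)
        for m in cluster.member_ids
        if m in member_psms
    ]
    if not forms:
        return None, 0.0
    (top, count), = Counter(forms).most_common(1)
    fraction = count / len(forms)
    if not fraction > 0.5:
        return None, fraction
    return top, fraction


def filter_multispectral(
    clusters: Sequence[Cluster],
    member_psms: Mapping[str, PSM],
    sequence_only: bool = False,
) -> list[Cluster]:
    """Keep clusters with >= 2 members and a defined majority peptidoform.

    Singleton clusters and clusters without a single peptidoform covering
    more than half of the member identifications are removed; order is
    preserved.
    """
    kept = []
    for cluster in clusters:
        if cluster.n_members < 2:
            continue
        form, _ = majority_peptidoform(cluster, member_psms, sequence_only)
        if form is not None:
            kept.append(cluster)
    return kept


def classify_representative(
    cluster: Cluster,
    member_psms: Mapping[str, PSM],
    representative_psm: PSM | None,
    sequence_only: bool = False,
) -> ClusterQuality:
    """Classify a representative spectrum's identification against its cluster.

    "majority" (high-quality): the representative's peptidoform equals the
    cluster's majority peptidoform. "minority": it equals some member's
    peptidoform but not the majority. "novel": it equals no member's
    peptidoform (possible for the peak-combining methods, whose consensus
    spectrum is not any member). "unidentified": the representative has no
    peptide-spectrum match.
    """
    majority, fraction = majority_peptidoform(cluster, member_psms, sequence_only)
    if representative_psm is None:
        category = "unidentified"
    else:
        rep_form = _form(representative_psm, sequence_only)
        member_forms = {
            _form(member_psms[m], sequence_only)
            for m in cluster.member_ids
            if m in member_psms
        }
        if majority is not None and rep_form == majority:
            category = "majority"
        elif rep_form in member_forms:
            category = "minority"
        else:
            category = "novel"
    return ClusterQuality(
        cluster_id=cluster.cluster_id,
        n_members=cluster.n_members,
        majority_peptidoform=majority,
        majority_fraction=fraction,
        representative_category=category,
    )


def quality_ratios(qualities: Sequence[ClusterQuality]) -> dict[str, float]:
    """Category fractions over clusters with an identified representative.

    Returns each category's fraction plus the aggregate "high_quality"
    (= majority) and "low_quality" (= minority + novel) ratios, and the
    counts used. The per-category fractions over identified representatives
    sum to 1.
    """
    if not qualities:
        return {}
    counts = Counter(q.representative_category for q in qualities)
    n_identified = sum(counts[c] for c in ("majority", "minority", "novel"))
    out: dict[str, float] = {
        "n_clusters": float(len(qualities)),
        "n_identified_representatives": float(n_identified),
        "n_unidentified_representatives": float(counts.get("unidentified", 0)),
    }
    if n_identified == 0:
        return out
    for category in ("majority", "minority", "novel"):
        out[category] = counts.get(category, 0) / n_identified
    out["high_quality"] = out["majority"]
    out["low_quality"] = out["minority"] + out["novel"]
    return out


def _size_bin(size: int) -> str:
    if size <= 5:
        return str(size)
    if size <= 10:
        return "5-10"
    if size <= 20:
        return "10-20"
    return ">20"


def score_by_cluster_size(
    clusters: Sequence[Cluster],
    representative_psms: Mapping[str, PSM],
) -> pd.DataFrame:
    """Mean representative score stratified by cluster size.

    ``representative_psms`` is keyed by cluster_id. Bins follow
    :data:`SIZE_BINS`; empty bins are emitted with n = 0 and an undefined
    (NaN) mean.
    """
    scores: dict[str, list[float]] = {b: [] for b in SIZE_BINS}
    for cluster in clusters:
        psm = representative_psms.get(cluster.cluster_id)
        if psm is None:
            continue
        scores[_size_bin(cluster.n_members)].append(psm.score)
    rows = [
        {
            "size_bin": b,
            "n": len(scores[b]),
            "mean_score": float(np.mean(scores[b])) if scores[b] else float("nan"),
        }
        for b in SIZE_BINS
    ]
    return pd.DataFrame(rows, columns=["size_bin", "n", "mean_score"])


def compare_methods(
    psms_a: Mapping[str, PSM], psms_b: Mapping[str, PSM]
) -> MethodComparison:
    """Compare two methods' identifications over their shared identifiers.

    For every key present in both tables: corroborative when the full
    peptidoforms agree, divergent_site when the sequences agree but the
    modification sites differ, divergent_peptide when the sequences differ.
    """
    shared = set(psms_a) & set(psms_b)
    corroborative = divergent_site = divergent_peptide = 0
    for key in shared:
        a, b = psms_a[key], psms_b[key]
        if a.peptide != b.peptide:
            divergent_peptide += 1
        elif a.peptidoform == b.peptidoform:
            corroborative += 1
        else:
            divergent_site += 1
    return MethodComparison(
        n_common_spectra=len(shared),
        corroborative=corroborative,
        divergent_site=divergent_site,
        divergent_peptide=divergent_peptide,
    )


def count_mod_sites(psms: Mapping[str, PSM], label: str) -> int:
    """Total modification sites carrying ``label`` across all PSMs.

    A PSM with two such sites contributes two.
    """
    return sum(
        sum(1 for m in psm.modifications if m.label == label) for psm in psms.values()
    )
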