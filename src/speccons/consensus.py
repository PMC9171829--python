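"""The four consensus methods for turning a spectrum cluster into one representative.

Two families are implemented:

* peak-combining — AVERAGE (merge nearby peaks across members, averaging
  m/z with intensity weights) and BIN (fixed 0.02 Th grid, discard bins
  populated by fewer than 25% of members, average within surviving bins);
* member-selecting — MOST (the medoid: maximal summed dot-product
  similarity to all other members) and BEST (the member with the best
  peptide-spectrum match score).

All tunables live in :class:`~speccons.model.ConsensusParams`.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np

from .model import (
    PSM,
    Cluster,
    ConsensusParams,
    ConsensusRecord,
    ConsensusRun,
    ContractError,
    Peak,
    Spectrum,
    UnidentifiedClusterError,
)

__all__ = [
    "merge_close_peaks",
    "consensus_average",
    "consensus_bin",
    "spectrum_dot_product",
    "consensus_most",
    "consensus_best",
    "consensus_precursor",
    "generate_consensus",
]

DEFAULT_PARAMS = ConsensusParams()


class PrecursorChargeWarning(UserWarning):
    """Members of one cluster disagree on the precursor charge."""


def merge_close_peaks(peaks: Sequence[Peak], tolerance: float) -> list[Peak]:
    """Greedily merge m/z-sorted peaks whose m/z lie within ``tolerance`` of
    the running intensity-weighted mean of the current group.

    Each group becomes one peak: m/z is the intensity-weighted mean of the
    group's m/z values, intensity the arithmetic mean of its intensities.
    A group of zero-intensity peaks falls back to an unweighted m/z mean.
    """
    if tolerance < 0:
        raise ContractError("tolerance must be >= 0")
    mzs = np.asarray([p[0] for p in peaks], dtype=float)
    if np.any(np.diff(mzs) < 0):
        raise ContractError("peaks must be sorted ascending by m/z")
    merged: list[Peak] = []
    group_mz: list[float] = []
    group_int: list[float] = []

    def flush() -> None:
        if group_mz:
            merged.append(Peak(_weighted_mean(group_mz, group_int), float(np.mean(group_int))))
            group_mz.clear()
            group_int.clear()

    for mz, intensity in peaks:
        if group_mz and abs(mz - _weighted_mean(group_mz, group_int)) > tolerance:
            flush()
        group_mz.append(float(mz))
        group_int.append(float(intensity))
    flush()
    merged.sort(key=lambda p: p.mz)
    return merged


def _weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    total = float(np.sum(weights))
    if total == 0.0:
        return float(np.mean(values))
    return float(np.dot(values, weights) / total)


def consensus_average(
    members: Sequence[Spectrum], params: ConsensusParams = DEFAULT_PARAMS
) -> Spectrum:
    """AVERAGE: pool all member peaks and merge those with close m/z.

    Member peak lists are concatenated, sorted by m/z, and passed through
    :func:`merge_close_peaks` with ``params.merge_tolerance``. The precursor
    is the median member precursor m/z with the modal charge.
    """
    if not members:
        raise ContractError("consensus_average requires at least one member")
    all_mz = np.concatenate([s.mz for s in members])
    all_int = np.concatenate([s.intensity for s in members])
    order = np.argsort(all_mz, kind="stable")
    pooled = [Peak(float(m), float(i)) for m, i in zip(all_mz[order], all_int[order])]
    merged = merge_close_peaks(pooled, params.merge_tolerance)
    precursor_mz, charge = consensus_precursor(members)
    return Spectrum.from_peaks(
        _consensus_id(members, "average"),
        merged,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
    )


def _bin_index(mz: np.ndarray, width: float) -> np.ndarray:
    # Half-open bins [i*w, (i+1)*w) anchored at m/z 0.
    return np.floor(np.asarray(mz, dtype=float) / width).astype(np.int64)


def consensus_bin(
    members: Sequence[Spectrum], params: ConsensusParams = DEFAULT_PARAMS
) -> Spectrum:
    """BIN: fixed-grid consensus with an occupancy filter.

    Every peak of every member is assigned to the half-open bin
    ``[i*w, (i+1)*w)`` with ``w = params.bin_width``. A bin's occupancy is
    the number of distinct members contributing at least one peak to it;
    bins whose occupancy fraction is strictly below ``params.min_fraction``
    are discarded. Each surviving bin emits one peak whose m/z and intensity
    are the unweighted means over all peaks in the bin; with
    ``params.bin_intensity_denominator = "members"`` the intensity sum is
    divided by the cluster size instead, so sparsely supported bins are
    downweighted.
    """
    if not members:
        raise ContractError("consensus_bin requires at least one member")
    n_members = len(members)
    bins: dict[int, dict] = {}
    for member_idx, spectrum in enumerate(members):
        for idx, mz, intensity in zip(
            _bin_index(spectrum.mz, params.bin_width), spectrum.mz, spectrum.intensity
        ):
            entry = bins.setdefault(int(idx), {"mz": [], "int": [], "members": set()})
            entry["mz"].append(float(mz))
            entry["int"].append(float(intensity))
            entry["members"].add(member_idx)
    peaks = []
    for idx in sorted(bins):
        entry = bins[idx]
        if len(entry["members"]) / n_members < params.min_fraction:
            continue
        if params.bin_intensity_denominator == "members":
            intensity = float(np.sum(entry["int"]) / n_members)
        else:
            intensity = float(np.mean(entry["int"]))
        peaks.append(Peak(float(np.mean(entry["mz"])), intensity))
    precursor_mz, charge = consensus_precursor(members)
    return Spectrum.from_peaks(
        _consensus_id(members, "bin"),
        peaks,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
    )


def _binned_unit_vector(spectrum: Spectrum, params: ConsensusParams) -> dict[int, float]:
    vec: dict[int, float] = {}
    for idx, intensity in zip(
        _bin_index(spectrum.mz, params.similarity_bin_width), spectrum.intensity
    ):
        vec[int(idx)] = vec.get(int(idx), 0.0) + float(intensity)
    if params.intensity_transform == "sqrt":
        vec = {k: float(np.sqrt(v)) for k, v in vec.items()}
    norm = float(np.sqrt(sum(v * v for v in vec.values())))
    if norm == 0.0:
        raise ContractError(
            f"spectrum {spectrum.spectrum_id!r} has all-zero intensities; "
            "normalized dot product undefined"
        )
    return {k: v / norm for k, v in vec.items()}


def spectrum_dot_product(
    a: Spectrum, b: Spectrum, params: ConsensusParams = DEFAULT_PARAMS
) -> float:
    """Normalized dot product of two spectra vectorized on a fixed m/z grid.

    Intensities falling in the same ``params.similarity_bin_width`` bin are
    summed, optionally sqrt-transformed, and each vector is scaled to unit
    Euclidean norm, so the result lies in [0, 1].
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ContractError("dot product requires spectra with at least one peak")
    va = _binned_unit_vector(a, params)
    vb = _binned_unit_vector(b, params)
    if len(vb) < len(va):
        va, vb = vb, va
    return float(sum(v * vb.get(k, 0.0) for k, v in va.items()))


def _break_tie(candidates: list[int], members: Sequence[Spectrum], params: ConsensusParams) -> int:
    if len(candidates) == 1:
        return candidates[0]
    if params.tie_break == "first_id":
        return min(candidates, key=lambda i: members[i].spectrum_id)
    rng = np.random.default_rng(params.seed)
    return int(rng.choice(candidates))


def consensus_most(
    members: Sequence[Spectrum], params: ConsensusParams = DEFAULT_PARAMS
) -> tuple[Spectrum, int]:
    """MOST: select the medoid member.

    For each member the dot-product similarities to every *other* member are
    summed (self-similarity excluded) and the member with the maximal sum is
    returned untouched, together with its index. Ties follow
    ``params.tie_break``.
    """
    if not members:
        raise ContractError("consensus_most requires at least one member")
    n = len(members)
    if n == 1:
        return members[0], 0
    vectors = [_binned_unit_vector(s, params) for s in members]
    sums = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            va, vb = vectors[i], vectors[j]
            if len(vb) < len(va):
                va, vb = vb, va
            sim = sum(v * vb.get(k, 0.0) for k, v in va.items())
            sums[i] += sim
            sums[j] += sim
    best = float(np.max(sums))
    candidates = [i for i in range(n) if np.isclose(sums[i], best, rtol=0, atol=1e-12)]
    pick = _break_tie(candidates, members, params)
    return members[pick], pick


def consensus_best(
    members: Sequence[Spectrum],
    psms: Mapping[str, PSM],
    params: ConsensusParams = DEFAULT_PARAMS,
) -> tuple[Spectrum, int]:
    """BEST: select the member with the best peptide-spectrum match score.

    "Best" follows ``params.score_direction``. Raises
    :class:`UnidentifiedClusterError` when no member has a PSM — the method
    is undefined for fully unidentified clusters.
    """
    if not members:
        raise ContractError("consensus_best requires at least one member")
    scored = [(i, psms[s.spectrum_id].score) for i, s in enumerate(members) if s.spectrum_id in psms]
    if not scored:
        raise UnidentifiedClusterError(
            "no cluster member has a peptide-spectrum match; BEST is undefined"
        )
    sign = 1.0 if params.score_direction == "higher" else -1.0
    best = max(sign * score for _, score in scored)
    candidates = [i for i, score in scored if sign * score == best]
    pick = _break_tie(candidates, members, params)
    return members[pick], pick


def consensus_precursor(members: Sequence[Spectrum]) -> tuple[float | None, int | None]:
    """Median precursor m/z and modal precursor charge of the members.

    Charge ties go to the smaller charge; unknown values are ignored. A
    :class:`PrecursorChargeWarning` is emitted when members disagree on the
    charge.
    """
    if not members:
        raise ContractError("consensus_precursor requires at least one member")
    mzs = [s.precursor_mz for s in members if s.precursor_mz is not None]
    precursor_mz = float(np.median(mzs)) if mzs else None
    charges = [s.precursor_charge for s in members if s.precursor_charge is not None]
    charge: int | None = None
    if charges:
        counts: dict[int, int] = {}
        for c in charges:
            counts[c] = counts.get(c, 0) + 1
        top = max(counts.values())
        charge = min(c for c, k in counts.items() if k == top)
        if len(counts) > 1:
            warnings.warn(
                f"cluster members carry {len(counts)} distinct precursor charges "
                f"{sorted(counts)}; using modal charge {charge}",
                PrecursorChargeWarning,
                stacklevel=2,
            )
    return precursor_mz, charge


def _consensus_id(members: Sequence[Spectrum], method: str) -> str:
    return f"consensus:{method}:{members[0].spectrum_id}"


def generate_consensus(
    clusters: Sequence[Cluster],
    spectra: Mapping[str, Spectrum],
    method: str,
    psms: Mapping[str, PSM] | None = None,
    params: ConsensusParams = DEFAULT_PARAMS,
) -> ConsensusRun:
    """Compute one :class:`ConsensusRecord` per cluster with the given method.

    ``spectra`` maps spectrum_id to :class:`Spectrum`; every cluster member
    must resolve. ``psms`` is required for method "best"; clusters whose
    members are all unidentified are then skipped and counted in
    ``n_skipped`` rather than failing the run.
    """
    if method not in ("average", "bin", "most", "best"):
        raise ContractError(f"unknown consensus method {method!r}")
    if method == "best" and psms is None:
        raise ContractError("method 'best' requires a PSM table")
    run = ConsensusRun(n_clusters_in=len(clusters))
    for cluster in clusters:
        members = []
        for member_id in cluster.member_ids:
            if member_id not in spectra:
                raise ContractError(
                    f"cluster {cluster.cluster_id!r}: member {member_id!r} "
                    "not found among the loaded spectra"
                )
            members.append(spectra[member_id])
        source_id: str | None = None
        if method == "average":
            spectrum = consensus_average(members, params)
        elif method == "bin":
            spectrum = consensus_bin(members, params)
        elif method == "most":
            spectrum, idx = consensus_most(members, params)
            source_id = cluster.member_ids[idx]
        else:
            try:
                spectrum, idx = consensus_best(members, psms, params)
            except UnidentifiedClusterError:
                run.n_skipped += 1
                run.warnings.append(
                    f"cluster {cluster.cluster_id!r}: all members unidentified; skipped"
                )
                continue
            source_id = cluster.member_ids[idx]
        run.records.append(
            ConsensusRecord(
                cluster_id=cluster.cluster_id,
                method=method,
                spectrum=spectrum,
                n_members=cluster.n_members,
                source_member_id=source_id,
            )
        )
    run.n_records_out = len(run.records)
    return run
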