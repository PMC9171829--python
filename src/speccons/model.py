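"""Domain types for clustered tandem mass spectra and their consensus representatives.

All m/z values are in Thomson (Th), intensities in arbitrary abundance units.
Spectra are centroided peak lists; peaks are kept sorted by m/z at all times.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

#: Methods implemented for turning a cluster into one representative spectrum.
CONSENSUS_METHODS = ("average", "bin", "most", "best")


class SpecconsError(Exception):
    """Base class for data and contract errors raised by this package."""


class ContractError(SpecconsError):
    """An operation's precondition was violated (e.g. empty cluster, unsorted peaks)."""


class ParseError(SpecconsError):
    """A file could not be parsed; the message names the file and line where known."""


class UnidentifiedClusterError(SpecconsError):
    """BEST cannot pick a representative: no cluster member has a peptide-spectrum match."""


class Peak(NamedTuple):
    """One centroided fragment peak."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS2 spectrum.

    Peaks are stored as two parallel float arrays sorted ascending by m/z;
    zero-intensity peaks are permitted and retained. ``precursor_charge`` may
    be ``None`` ("unknown") and is never imputed.
    """

    spectrum_id: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    retention_time: float | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or inten.shape != mz.shape:
            raise ContractError("mz and intensity must be 1-D arrays of equal length")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])
        if not self.spectrum_id:
            raise ContractError("spectrum_id must be non-empty")
        if mz.size and mz.min() <= 0:
            raise ContractError(f"spectrum {self.spectrum_id!r}: all m/z must be > 0")
        if inten.size and inten.min() < 0:
            raise ContractError(f"spectrum {self.spectrum_id!r}: intensities must be >= 0")
        if self.precursor_mz is not None and self.precursor_mz <= 0:
            raise ContractError(f"spectrum {self.spectrum_id!r}: precursor_mz must be > 0")

    @classmethod
    def from_peaks(cls, spectrum_id: str, peaks: Sequence[tuple[float, float]], **kwargs) -> "Spectrum":
        arr = np.asarray(peaks, dtype=float).reshape(-1, 2)
        return cls(spectrum_id, arr[:, 0], arr[:, 1], **kwargs)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def peaks_equal(self, other: "Spectrum", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (
            self.n_peaks == other.n_peaks
            and np.allclose(self.mz, other.mz, rtol=rtol, atol=atol)
            and np.allclose(self.intensity, other.intensity, rtol=rtol, atol=atol)
        )


@dataclass(frozen=True)
class Cluster:
    """A cluster identifier and the ordered, duplicate-free list of member spectrum ids."""

    cluster_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(self.member_ids)
        object.__setattr__(self, "member_ids", members)
        if not members:
            raise ContractError(f"cluster {self.cluster_id!r} has no members")
        if len(set(members)) != len(members):
            raise ContractError(f"cluster {self.cluster_id!r} has duplicate member ids")

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


class Modification(NamedTuple):
    """A localized modification: 1-based residue position (0 = N-terminus), label, mass delta in Da."""

    position: int
    label: str
    mass_delta: float


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with its modification sites.

    Two peptidoforms are equal iff the sequence and the full sorted
    (position, label) site list both match.
    """

    peptide: str
    mod_sites: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        sites = tuple(sorted(self.mod_sites))
        object.__setattr__(self, "mod_sites", sites)
        for pos, _ in sites:
            if not 0 <= pos <= len(self.peptide):
                raise ContractError(
                    f"modification position {pos} outside peptide of length {len(self.peptide)}"
                )


@dataclass(frozen=True)
class PSM:
    """A rank-1 peptide-spectrum match."""

    spectrum_id: str
    peptide: str
    score: float
    modifications: tuple[Modification, ...] = ()
    q_value: float | None = None
    is_decoy: bool | None = None

    def __post_init__(self) -> None:
        mods = tuple(Modification(*m) for m in self.modifications)
        object.__setattr__(self, "modifications", mods)
        for mod in mods:
            if not 0 <= mod.position <= len(self.peptide):
                raise ContractError(
                    f"PSM {self.spectrum_id!r}: modification position {mod.position} "
                    f"outside peptide of length {len(self.peptide)}"
                )

    @property
    def peptidoform(self) -> Peptidoform:
        return Peptidoform(self.peptide, tuple((m.position, m.label) for m in self.modifications))


@dataclass(frozen=True)
class ConsensusParams:
    """Tunable parameters of the consensus methods.

    bin_width
        Width (Th) of the half-open m/z bins [i*w, (i+1)*w) used by BIN.
    min_fraction
        BIN occupancy threshold: a bin is discarded when the fraction of
        distinct members contributing to it is strictly below this value.
    merge_tolerance
        AVERAGE peak-merge window (Th) around the running intensity-weighted
        group mean m/z.
    similarity_bin_width
        Bin width (Th) for vectorizing spectra in the dot-product similarity
        used by MOST.
    intensity_transform
        "none" or "sqrt", applied to binned intensities before normalization
        in the similarity.
    score_direction
        Whether larger ("higher") or smaller ("lower") search-engine scores
        are better, for BEST.
    tie_break
        "first_id" picks the lexicographically smallest spectrum id among
        tied candidates; "random" draws one with the given seed.
    bin_intensity_denominator
        "peaks" (default) divides each surviving bin's summed intensity by
        the number of contributing peaks; "members" divides by the cluster
        size, downweighting bins few members support.
    """

    bin_width: float = 0.02
    min_fraction: float = 0.25
    merge_tolerance: float = 0.02
    similarity_bin_width: float = 0.02
    intensity_transform: str = "none"
    score_direction: str = "higher"
    tie_break: str = "first_id"
    seed: int | None = None
    bin_intensity_denominator: str = "peaks"

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.similarity_bin_width <= 0:
            raise ContractError("bin widths must be > 0")
        if not 0 < self.min_fraction <= 1:
            raise ContractError("min_fraction must be in (0, 1]")
        if self.merge_tolerance < 0:
            raise ContractError("merge_tolerance must be >= 0")
        if self.intensity_transform not in ("none", "sqrt"):
            raise ContractError("intensity_transform must be 'none' or 'sqrt'")
        if self.score_direction not in ("higher", "lower"):
            raise ContractError("score_direction must be 'higher' or 'lower'")
        if self.tie_break not in ("first_id", "random"):
            raise ContractError("tie_break must be 'first_id' or 'random'")
        if self.tie_break == "random" and self.seed is None:
            raise ContractError("tie_break='random' requires an explicit seed")
        if self.bin_intensity_denominator not in ("peaks", "members"):
            raise ContractError("bin_intensity_denominator must be 'peaks' or 'members'")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ConsensusRecord:
    """One representative spectrum for one cluster.

    ``source_member_id`` is set for the member-selecting methods (MOST, BEST),
    whose ``spectrum`` is the untouched member spectrum; it is ``None`` for
    the peak-combining methods (AVERAGE, BIN).
    """

    cluster_id: str
    method: str
    spectrum: Spectrum
    n_members: int
    source_member_id: str | None = None

    def __post_init__(self) -> None:
        if self.method not in CONSENSUS_METHODS:
            raise ContractError(f"unknown consensus method {self.method!r}")
        if self.n_members < 1:
            raise ContractError("n_members must be >= 1")


@dataclass(frozen=True)
class ClusterQuality:
    """Per-cluster classification of a representative spectrum's identification.

    representative_category is "majority" when the representative's
    peptidoform equals the cluster's majority peptidoform (a high-quality
    representative), "minority" when it matches some member but not the
    majority, "novel" when it matches no member, and "unidentified" when the
    representative has no peptide-spectrum match.
    """

    cluster_id: str
    n_members: int
    majority_peptidoform: Peptidoform | None
    majority_fraction: float
    representative_category: str

    def __post_init__(self) -> None:
        if self.representative_category not in ("majority", "minority", "novel", "unidentified"):
            raise ContractError(f"unknown category {self.representative_category!r}")
        if self.majority_peptidoform is not None and not self.majority_fraction > 0.5:
            raise ContractError("majority peptidoform set but fraction not > 0.5")


@dataclass(frozen=True)
class MethodComparison:
    """Counts comparing two methods' identifications over their shared spectra.

    corroborative: identical peptidoforms; divergent_site: same sequence but
    different modification sites; divergent_peptide: different sequences.
    The three counts partition n_common_spectra.
    """

    n_common_spectra: int
    corroborative: int
    divergent_site: int
    divergent_peptide: int

    def __post_init__(self) -> None:
        if self.corroborative + self.divergent_site + self.divergent_peptide != self.n_common_spectra:
            raise ContractError("comparison counts must partition the shared spectra")


@dataclass
class ConsensusRun:
    """Bookkeeping for one consensus-generation pass."""

    records: list[ConsensusRecord] = field(default_factory=list)
    n_clusters_in: int = 0
    n_records_out: int = 0
    n_skipped: int = 0
    warnings: list[str] = field(default_factory=list)
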