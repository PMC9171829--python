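"""Seeded generator of synthetic spectrum clusters for testing.

Each cluster is a set of replicate spectra of a shared template: the
template's peaks are subjected to dropout, m/z jitter and multiplicative
intensity noise, and low-intensity noise peaks are added. Optionally a
fraction of clusters receive one contaminant member drawn from a different
template, producing the mixed clusters the evaluation statistics are about.
Every member carries a synthetic peptide-spectrum match whose score grows
with the member's similarity to its own template. No fragmentation physics
is modelled — peptidoform labels are opaque strings standing in for real
identifications.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .consensus import spectrum_dot_product
from .io import PsmTable, write_mgf, write_psms
from .model import PSM, Cluster, ConsensusParams, SpecconsError, Spectrum

__all__ = ["SimConfig", "MemberTruth", "ClusterTruth", "SyntheticDataset",
           "make_template", "make_replicate", "make_dataset"]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the cluster simulator.

    Defaults emulate well-clustered replicate MS2 spectra: ~40 fragment
    peaks per analyte in 100-1500 Th, m/z jitter (sd 0.005 Th) well inside a
    0.02 Th bin, 20% multiplicative intensity noise, 10% peak dropout and 5
    low-intensity noise peaks per replicate. ``members_per_cluster`` may be
    an int or an inclusive ``(min, max)`` range. The seed is mandatory —
    the generator has no hidden entropy.
    """

    n_clusters: int
    members_per_cluster: int | tuple[int, int]
    seed: int
    n_template_peaks: int = 40
    mz_range: tuple[float, float] = (100.0, 1500.0)
    intensity_log_mean: float = 6.0
    intensity_log_sd: float = 1.0
    mz_jitter_sd: float = 0.005
    intensity_cv: float = 0.2
    dropout_p: float = 0.1
    n_noise_peaks: int = 5
    contamination_fraction: float = 0.0
    min_peak_spacing: float = 0.04
    peptide_length: int = 12

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if not lo < hi:
            raise SpecconsError("mz_range must satisfy min < max")
        for name in ("dropout_p", "contamination_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise SpecconsError(f"{name} must be in [0, 1]")
        if self.seed is None:
            raise SpecconsError("seed is mandatory")
        needed = (self.n_template_peaks - 1) * self.min_peak_spacing
        if needed >= hi - lo:
            raise SpecconsError(
                f"cannot place {self.n_template_peaks} peaks with spacing "
                f"{self.min_peak_spacing} Th in a {hi - lo} Th range"
            )

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class MemberTruth:
    """Ground truth for one generated member spectrum."""

    is_contaminant: bool
    peptidoform_label: str


@dataclass(frozen=True)
class ClusterTruth:
    """Ground truth for one generated cluster: its template and its members."""

    template: Spectrum
    members: dict[str, MemberTruth]


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth, writable as io-compatible files."""

    config: SimConfig
    spectra: list[Spectrum]
    clusters: list[Cluster]
    psms: PsmTable
    ground_truth: dict[str, ClusterTruth] = field(default_factory=dict)

    @property
    def spectrum_index(self) -> dict[str, Spectrum]:
        return {s.spectrum_id: s for s in self.spectra}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write spectra.mgf, clusters.tsv, psms.tsv and ground_truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mgf": out / "spectra.mgf",
            "clusters": out / "clusters.tsv",
            "psms": out / "psms.tsv",
            "ground_truth": out / "ground_truth.json",
        }
        write_mgf(self.spectra, paths["mgf"])
        with open(paths["clusters"], "w", encoding="utf-8") as handle:
            handle.write("cluster_id\tspectrum_id\n")
            for cluster in self.clusters:
                for member in cluster.member_ids:
                    handle.write(f"{cluster.cluster_id}\t{member}\n")
        write_psms(self.psms, paths["psms"])
        truth = {
            cid: {
                "template_peaks": [[m, i] for m, i in zip(ct.template.mz, ct.template.intensity)],
                "members": {
                    mid: {"is_contaminant": mt.is_contaminant, "label": mt.peptidoform_label}
                    for mid, mt in ct.members.items()
                },
            }
            for cid, ct in self.ground_truth.items()
        }
        with open(paths["ground_truth"], "w", encoding="utf-8") as handle:
            json.dump(truth, handle, indent=1)
        return paths


def _random_peptide(config: SimConfig, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AMINO_ACIDS), size=config.peptide_length))


def make_template(
    config: SimConfig, rng: np.random.Generator, template_id: str = "template"
) -> tuple[Spectrum, str]:
    """Draw a template spectrum and its synthetic peptidoform label.

    m/z values are uniform in ``mz_range`` subject to a minimum adjacent
    spacing of ``min_peak_spacing`` (so distinct template peaks cannot share
    a 0.02 Th bin); intensities are log-normal.
    """
    n = config.n_template_peaks
    lo, hi = config.mz_range
    spacing = config.min_peak_spacing
    # Sorted uniforms in a shrunken range plus a spacing ramp give uniform
    # positions conditioned on the minimum-gap constraint.
    base = np.sort(rng.uniform(lo, hi - (n - 1) * spacing, size=n))
    mz = base + spacing * np.arange(n)
    intensity = rng.lognormal(config.intensity_log_mean, config.intensity_log_sd, size=n)
    spectrum = Spectrum(
        spectrum_id=template_id,
        mz=mz,
        intensity=intensity,
        precursor_mz=float(rng.uniform(400.0, 1200.0)),
        precursor_charge=int(rng.choice([2, 3])),
    )
    return spectrum, _random_peptide(config, rng)


def make_replicate(
    template: Spectrum,
    config: SimConfig,
    rng: np.random.Generator,
    spectrum_id: str,
) -> Spectrum:
    """Generate one noisy replicate of a template spectrum.

    Each template peak survives with probability ``1 - dropout_p``; survivors
    get Gaussian m/z jitter and log-normal multiplicative intensity noise.
    ``n_noise_peaks`` peaks are added uniformly over the m/z range, with
    intensities below the template's 25th intensity percentile.
    """
    keep = rng.random(template.n_peaks) >= config.dropout_p
    mz = template.mz[keep] + rng.normal(0.0, config.mz_jitter_sd, size=int(keep.sum()))
    intensity = template.intensity[keep] * rng.lognormal(
        0.0, config.intensity_cv, size=int(keep.sum())
    )
    if config.n_noise_peaks:
        lo, hi = config.mz_range
        noise_cap = float(np.percentile(template.intensity, 25))
        noise_mz = rng.uniform(lo, hi, size=config.n_noise_peaks)
        noise_int = rng.uniform(0.0, noise_cap, size=config.n_noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        intensity = np.concatenate([intensity, noise_int])
    mz = np.clip(mz, 1e-6, None)
    return Spectrum(
        spectrum_id=spectrum_id,
        mz=mz,
        intensity=intensity,
        precursor_mz=template.precursor_mz,
        precursor_charge=template.precursor_charge,
    )


def make_dataset(config: SimConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate clusters of replicate spectra with member PSMs and ground truth.

    The first ``round(contamination_fraction * n_clusters)`` clusters have
    their last member replaced by a replicate of an independently drawn
    contaminant template; contaminants carry their own template's peptidoform
    label. Member PSM scores are ``100 * similarity_to_own_template +
    Normal(0, 2)`` so BEST has a meaningful signal. If ``out_dir`` is given
    the io-compatible files are written there as well.
    """
    rng = np.random.default_rng(config.seed)
    sim_params = ConsensusParams()
    n_contaminated = int(round(config.contamination_fraction * config.n_clusters))
    spectra: list[Spectrum] = []
    clusters: list[Cluster] = []
    psms = PsmTable(score_direction="higher")
    truth: dict[str, ClusterTruth] = {}

    for c in range(config.n_clusters):
        cluster_id = f"cluster_{c + 1:04d}"
        template, label = make_template(config, rng, template_id=f"{cluster_id}:template")
        if isinstance(config.members_per_cluster, int):
            n_members = config.members_per_cluster
        else:
            lo, hi = config.members_per_cluster
            n_members = int(rng.integers(lo, hi + 1))
        contaminate = c < n_contaminated and n_members >= 2
        members: dict[str, MemberTruth] = {}
        member_ids = []
        for m in range(n_members):
            member_id = f"{cluster_id}:member_{m + 1}"
            is_contaminant = contaminate and m == n_members - 1
            if is_contaminant:
                source, source_label = make_template(
                    config, rng, template_id=f"{cluster_id}:contaminant_template"
                )
            else:
                source, source_label = template, label
            replicate = make_replicate(source, config, rng, member_id)
            similarity = spectrum_dot_product(replicate, source, sim_params)
            psms[member_id] = PSM(
                spectrum_id=member_id,
                peptide=source_label,
                score=float(100.0 * similarity + rng.normal(0.0, 2.0)),
            )
            spectra.append(replicate)
            member_ids.append(member_id)
            members[member_id] = MemberTruth(is_contaminant, source_label)
        clusters.append(Cluster(cluster_id, tuple(member_ids)))
        truth[cluster_id] = ClusterTruth(template=template, members=members)

    dataset = SyntheticDataset(
        config=config, spectra=spectra, clusters=clusters, psms=psms, ground_truth=truth
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
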