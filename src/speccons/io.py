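"""Readers and writers for the formats the package touches.

MGF peak lists go through :mod:`pyteomics.mgf`; cluster assignments are read
either from a normalized two-column TSV or from the blank-line-delimited
dialect emitted by common clustering tools; peptide-spectrum matches come
from a flat TSV with an optional ``#score_direction=`` pragma line.
"""

from __future__ import annotations

import math
import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _pymgf

from .model import (
    PSM,
    Cluster,
    ConsensusRecord,
    Modification,
    ParseError,
    Spectrum,
)

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_clusters",
    "read_id_map",
    "remap_member_ids",
    "read_psms",
    "write_psms",
    "PsmTable",
]


def _validate_mgf_structure(path: str | os.PathLike) -> None:
    """Pre-scan an MGF file so structural errors can name their line number.

    Checks BEGIN IONS / END IONS pairing and that non key=value lines inside
    a block are numeric peak lines (m/z, intensity, optional charge).
    """
    in_block = False
    begin_line = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise ParseError(
                        f"{path}: line {lineno}: BEGIN IONS inside an open block "
                        f"(missing END IONS for block starting at line {begin_line})"
                    )
                in_block = True
                begin_line = lineno
                continue
            if line == "END IONS":
                if not in_block:
                    raise ParseError(f"{path}: line {lineno}: END IONS without BEGIN IONS")
                in_block = False
                continue
            if not in_block or "=" in line:
                continue
            fields = line.split()
            if not 1 <= len(fields) <= 3 or not all(_is_number(f) for f in fields):
                raise ParseError(f"{path}: line {lineno}: malformed peak line {line!r}")
    if in_block:
        raise ParseError(
            f"{path}: missing END IONS for block starting at line {begin_line}"
        )


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_mgf(path: str | os.PathLike) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    One spectrum per BEGIN IONS/END IONS block. The spectrum id is the TITLE
    verbatim when present, otherwise ``"<basename>:index=<ordinal>"`` with a
    1-based ordinal. Peaks are sorted by m/z on load; zero-intensity peaks
    are retained.
    """
    _validate_mgf_structure(path)
    stem = Path(path).stem
    spectra: list[Spectrum] = []
    with _pymgf.MGF(str(path), convert_arrays=1) as reader:
        for ordinal, entry in enumerate(reader, start=1):
            params = entry.get("params", {})
            title = params.get("title")
            spectrum_id = str(title) if title else f"{stem}:index={ordinal}"
            pepmass = params.get("pepmass")
            precursor_mz = None
            if pepmass is not None:
                precursor_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge")
            precursor_charge = int(charge[0]) if charge else None
            rt = params.get("rtinseconds")
            spectra.append(
                Spectrum(
                    spectrum_id=spectrum_id,
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float),
                    precursor_mz=precursor_mz,
                    precursor_charge=precursor_charge,
                    retention_time=float(rt) if rt is not None else None,
                )
            )
    return spectra


def _spectrum_to_entry(spectrum: Spectrum, title: str) -> dict:
    params: dict = {"title": title}
    if spectrum.precursor_mz is not None:
        params["pepmass"] = spectrum.precursor_mz
    if spectrum.precursor_charge is not None:
        c = spectrum.precursor_charge
        params["charge"] = f"{abs(c)}{'+' if c >= 0 else '-'}"
    if spectrum.retention_time is not None:
        params["rtinseconds"] = spectrum.retention_time
    return {
        "m/z array": spectrum.mz,
        "intensity array": spectrum.intensity,
        "params": params,
    }


def write_mgf(
    spectra: Iterable[Spectrum | ConsensusRecord], path: str | os.PathLike
) -> None:
    """Write spectra or consensus records to an MGF file.

    m/z values are written with 4 decimal places and intensities with 4
    significant digits. For :class:`ConsensusRecord` inputs the TITLE encodes
    ``cluster=<cluster_id>;method=<method>;size=<n_members>``.
    """
    entries = []
    for item in spectra:
        if isinstance(item, ConsensusRecord):
            title = f"cluster={item.cluster_id};method={item.method};size={item.n_members}"
            entries.append(_spectrum_to_entry(item.spectrum, title))
        else:
            entries.append(_spectrum_to_entry(item, item.spectrum_id))
    with open(path, "w", encoding="utf-8") as handle:
        _pymgf.write(
            entries,
            handle,
            key_order=["title", "pepmass", "charge", "rtinseconds"],
            fragment_format="{:.4f} {:.4g}",
            use_numpy=False,
        )


def read_clusters(path: str | os.PathLike, dialect: str = "tsv") -> list[Cluster]:
    """Read cluster assignments.

    dialect "tsv": header ``cluster_id<TAB>spectrum_id``, one row per member.
    dialect "maracluster": clusters separated by blank lines, member lines
    ``<file><TAB><scan>``; spectrum ids become ``"<basename>:scan=<scan>"``
    and cluster ids ``"cluster_<ordinal>"`` (1-based). Clusters are returned
    in file order; singletons are retained. A spectrum id appearing in more
    than one cluster (or twice in one) is an error.
    """
    if dialect == "tsv":
        clusters = _read_clusters_tsv(path)
    elif dialect == "maracluster":
        clusters = _read_clusters_maracluster(path)
    else:
        raise ValueError(f"unknown cluster dialect {dialect!r}")
    seen: dict[str, str] = {}
    for cluster in clusters:
        for member in cluster.member_ids:
            if member in seen:
                raise ParseError(
                    f"{path}: spectrum {member!r} appears in clusters "
                    f"{seen[member]!r} and {cluster.cluster_id!r}; "
                    "a spectrum belongs to exactly one cluster"
                )
            seen[member] = cluster.cluster_id
    return clusters


def _read_clusters_tsv(path: str | os.PathLike) -> list[Cluster]:
    if os.path.getsize(path) == 0:
        return []
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cluster_id", "spectrum_id"):
        if col not in table.columns:
            raise ParseError(f"{path}: missing mandatory column {col!r}")
    members: dict[str, list[str]] = {}
    for cluster_id, spectrum_id in zip(table["cluster_id"], table["spectrum_id"]):
        bucket = members.setdefault(cluster_id, [])
        if spectrum_id in bucket:
            raise ParseError(
                f"{path}: duplicate member {spectrum_id!r} in cluster {cluster_id!r}"
            )
        bucket.append(spectrum_id)
    return [Cluster(cid, tuple(ids)) for cid, ids in members.items()]


def _read_clusters_maracluster(path: str | os.PathLike) -> list[Cluster]:
    clusters: list[Cluster] = []
    block: list[str] = []

    def flush() -> None:
        if block:
            clusters.append(Cluster(f"cluster_{len(clusters) + 1}", tuple(block)))
            block.clear()

    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected '<file><TAB><scan>', got {line!r}"
                )
            stem = Path(fields[0]).stem
            scan = fields[1].strip()
            block.append(f"{stem}:scan={scan}")
    flush()
    return clusters


def read_id_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV (``from_id<TAB>to_id``) remapping spectrum ids."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: id map needs two columns (from_id, to_id)")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def remap_member_ids(clusters: Sequence[Cluster], id_map: Mapping[str, str]) -> list[Cluster]:
    """Apply an id map to cluster member ids; ids absent from the map pass through."""
    return [
        Cluster(c.cluster_id, tuple(id_map.get(m, m) for m in c.member_ids))
        for c in clusters
    ]


class PsmTable(dict):
    """Mapping spectrum_id -> :class:`PSM`, carrying the table's score direction."""

    def __init__(self, *args, score_direction: str = "higher", **kwargs) -> None:
        super().__init__(*args, **kwargs)
        self.score_direction = score_direction


def _parse_modifications(token) -> tuple[Modification, ...]:
    if token is None or (isinstance(token, float) and math.isnan(token)) or token == "":
        return ()
    mods = []
    for piece in str(token).split(";"):
        piece = piece.strip()
        if not piece:
            continue
        parts = piece.split(":")
        if len(parts) != 3:
            raise ParseError(f"unparseable modification token {piece!r} (want 'pos:label:delta')")
        try:
            mods.append(Modification(int(parts[0]), parts[1], float(parts[2])))
        except ValueError as exc:
            raise ParseError(f"unparseable modification token {piece!r}: {exc}") from exc
    return tuple(mods)


def read_psms(path: str | os.PathLike) -> PsmTable:
    """Read a PSM TSV into a :class:`PsmTable` keyed by spectrum id.

    The file may start with a pragma line ``#score_direction=higher|lower``
    (default higher). Mandatory columns: spectrum_id, peptide, score.
    Optional: modifications (semicolon-separated ``pos:label:delta``),
    q_value, is_decoy. When a spectrum id occurs on several rows the
    better-scoring row is kept (ties: first occurrence).
    """
    direction = "higher"
    skiprows = 0
    with open(path, encoding="utf-8") as handle:
        first = handle.readline().strip()
    if first.startswith("#score_direction="):
        direction = first.split("=", 1)[1].strip()
        if direction not in ("higher", "lower"):
            raise ParseError(f"{path}: invalid score direction {direction!r}")
        skiprows = 1
    table = pd.read_csv(path, sep="\t", skiprows=skiprows, dtype={"spectrum_id": str, "peptide": str})
    for col in ("spectrum_id", "peptide", "score"):
        if col not in table.columns:
            raise ParseError(f"{path}: missing mandatory column {col!r}")

    better = (lambda a, b: a > b) if direction == "higher" else (lambda a, b: a < b)
    psms = PsmTable(score_direction=direction)
    for row in table.itertuples(index=False):
        q_value = getattr(row, "q_value", None)
        if q_value is not None and math.isnan(q_value):
            q_value = None
        is_decoy = getattr(row, "is_decoy", None)
        if is_decoy is not None and not isinstance(is_decoy, bool):
            is_decoy = None if (isinstance(is_decoy, float) and math.isnan(is_decoy)) else bool(is_decoy)
        psm = PSM(
            spectrum_id=str(row.spectrum_id),
            peptide=str(row.peptide),
            score=float(row.score),
            modifications=_parse_modifications(getattr(row, "modifications", None)),
            q_value=None if q_value is None else float(q_value),
            is_decoy=is_decoy,
        )
        held = psms.get(psm.spectrum_id)
        if held is None or better(psm.score, held.score):
            psms[psm.spectrum_id] = psm
    return psms


def write_psms(
    psms: Mapping[str, PSM] | Iterable[PSM],
    path: str | os.PathLike,
    score_direction: str | None = None,
) -> None:
    """Write PSMs to the TSV dialect read by :func:`read_psms`."""
    items = list(psms.values()) if isinstance(psms, Mapping) else list(psms)
    if score_direction is None:
        score_direction = getattr(psms, "score_direction", "higher")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"#score_direction={score_direction}\n")
        handle.write("spectrum_id\tpeptide\tmodifications\tscore\tq_value\tis_decoy\n")
        for psm in items:
            mods = ";".join(f"{m.position}:{m.label}:{m.mass_delta:g}" for m in psm.modifications)
            q = "" if psm.q_value is None else f"{psm.q_value:g}"
            decoy = "" if psm.is_decoy is None else str(psm.is_decoy)
            handle.write(
                f"{psm.spectrum_id}\t{psm.peptide}\t{mods}\t{psm.score:g}\t{q}\t{decoy}\n"
            )
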