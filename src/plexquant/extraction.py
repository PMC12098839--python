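"""Reporter-ion extraction: match MS2 peaks to TMTpro channels.

For each MS2 scan the 18 reporter channels are matched against observed
centroid peaks under a peak-match tolerance (PMT).  The assignment rule is
nearest-by-m/z within +/- tolerance, ties broken by higher intensity.  A
single observed peak may be assigned to two channels: under detector
saturation an isotopolog pair coalesces into one merged peak that, at a
wide tolerance (0.003 Da), falls inside both channels' windows — the
narrow 0.001 Da tolerance is what keeps a merged peak out of both.

Per-channel observations carry intensity, instrument-reported noise,
signal-to-noise (S/N = intensity/noise) and resolving power; these feed
the saturation/low-signal PSM filter downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from plexquant.reference import channel_labels, reporter_table

__all__ = [
    "Peak",
    "Ms2Scan",
    "ReporterObservation",
    "PsmQuantRecord",
    "match_reporter_ions",
    "build_psm_table",
    "read_psm_table",
    "write_psm_table",
    "read_mzml_scans",
    "read_scan_tsv",
    "write_scan_tsv",
]

N_CHANNELS = 18


@dataclass(frozen=True)
class Peak:
    """One centroid peak: m/z, intensity, optional noise and resolution."""

    mz: float
    intensity: float
    noise: Optional[float] = None
    resolution: Optional[float] = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")
        if self.noise is not None and self.noise <= 0:
            raise ValueError("peak noise must be positive when present")


@dataclass
class Ms2Scan:
    """A centroided MS2 scan; peaks kept sorted by m/z."""

    scan_id: str
    peaks: list[Peak]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)


@dataclass(frozen=True)
class ReporterObservation:
    """One channel's matched (or missing) reporter peak within a scan."""

    channel_label: str
    matched: bool
    mz_observed: Optional[float] = None
    delta_mz: Optional[float] = None
    intensity: float = 0.0
    noise: Optional[float] = None
    sn: float = 0.0
    resolution: Optional[float] = None


@dataclass
class PsmQuantRecord:
    """One PSM's 18-channel reporter quantitation.

    ``observations`` holds exactly 18 entries in ascending channel m/z
    order.  ``total_sn`` is the summed S/N over all channels (unmatched
    channels contribute 0); ``min_resolution`` is the minimum resolving
    power over matched observations that report one, or None.
    """

    psm_id: str
    scan_id: str
    peptide_sequence: str
    protein_ids: tuple[str, ...]
    observations: tuple[ReporterObservation, ...]
    sn_estimated: bool = False

    def __post_init__(self):
        if len(self.observations) != N_CHANNELS:
            raise ValueError(
                f"PSM {self.psm_id}: expected {N_CHANNELS} observations, "
                f"got {len(self.observations)}"
            )

    @property
    def total_sn(self) -> float:
        return sum(o.sn for o in self.observations)

    @property
    def min_resolution(self) -> Optional[float]:
        res = [
            o.resolution
            for o in self.observations
            if o.matched and o.resolution is not None
        ]
        return min(res) if res else None

    def sn_vector(self) -> list[float]:
        return [o.sn for o in self.observations]


def match_reporter_ions(
    scan: Ms2Scan,
    tolerance: float,
    default_noise: Optional[float] = None,
) -> tuple[ReporterObservation, ...]:
    """Match the scan's peaks to the 18 reporter channels.

    Parameters
    ----------
    scan : Ms2Scan
        Centroided MS2 scan.
    tolerance : float
        Peak-match tolerance in Da (symmetric window around each
        channel's exact m/z); typical values 0.001 (quantitation) and
        0.003 (wide/diagnostic).
    default_noise : float, optional
        Per-scan noise used for peaks lacking an instrument noise value
        (e.g. plain mzML without vendor noise arrays).  When it is used
        the downstream record should be flagged ``sn_estimated``.

    Returns
    -------
    tuple of 18 ReporterObservation in channel order.  For each channel
    the in-window peak minimizing \\|mz - exact_mz\\| is assigned (ties by
    higher intensity).  A peak may serve two channels.  Unmatched
    channels get sn = 0.
    """
    if not (tolerance > 0) or math.isnan(tolerance):
        raise ValueError(f"tolerance must be a positive number, got {tolerance}")
    observations = []
    for chan in reporter_table():
        best: Optional[Peak] = None
        best_key: Optional[tuple[float, float]] = None
        for peak in scan.peaks:
            if peak.mz < chan.exact_mz - tolerance:
                continue
            if peak.mz > chan.exact_mz + tolerance:
                break
            key = (abs(peak.mz - chan.exact_mz), -peak.intensity)
            if best_key is None or key < best_key:
                best, best_key = peak, key
        if best is None:
            observations.append(
                ReporterObservation(channel_label=chan.label, matched=False)
            )
        else:
            noise = best.noise if best.noise is not None else default_noise
            sn = best.intensity / noise if noise else 0.0
            observations.append(
                ReporterObservation(
                    channel_label=chan.label,
                    matched=True,
                    mz_observed=best.mz,
                    delta_mz=best.mz - chan.exact_mz,
                    intensity=best.intensity,
                    noise=noise,
                    sn=sn,
                    resolution=best.resolution,
                )
            )
    return tuple(observations)


def build_psm_table(
    scans: Iterable[Ms2Scan],
    psm_assignments: Sequence[Mapping],
    tolerance: float,
    default_noise: Optional[float] = None,
) -> list[PsmQuantRecord]:
    """Assemble one PsmQuantRecord per PSM assignment.

    ``psm_assignments`` rows are mappings with keys ``psm_id``,
    ``scan_id``, ``peptide`` and ``protein`` (protein may be a single id
    or a ';'-separated group).  Two PSMs sharing a scan get identical
    observations.

    Raises
    ------
    KeyError
        If an assignment references a scan_id absent from ``scans``.
    """
    scan_index = {s.scan_id: s for s in scans}
    matched_cache: dict[str, tuple[ReporterObservation, ...]] = {}
    records = []
    for row in psm_assignments:
        psm_id = str(row["psm_id"])
        scan_id = str(row["scan_id"])
        if scan_id not in scan_index:
            raise KeyError(
                f"PSM {psm_id} references unknown scan_id {scan_id!r}"
            )
        if scan_id not in matched_cache:
            matched_cache[scan_id] = match_reporter_ions(
                scan_index[scan_id], tolerance, default_noise=default_noise
            )
        proteins = str(row["protein"]).split(";")
        has_native_noise = any(
            p.noise is not None for p in scan_index[scan_id].peaks
        )
        records.append(
            PsmQuantRecord(
                psm_id=psm_id,
                scan_id=scan_id,
                peptide_sequence=str(row["peptide"]),
                protein_ids=tuple(proteins),
                observations=matched_cache[scan_id],
                sn_estimated=default_noise is not None and not has_native_noise,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Tabular serialization: one row per PSM, per-channel column quartets.

def _channel_columns() -> list[str]:
    cols = []
    for label in channel_labels():
        cols.extend(
            [f"{label}_mz", f"{label}_intensity", f"{label}_noise", f"{label}_resolution"]
        )
    return cols


def write_psm_table(records: Sequence[PsmQuantRecord], path) -> None:
    """Write PSM records to TSV (UTF-8, 'NA' for absent values)."""
    rows = []
    for rec in records:
        row: dict = {
            "psm_id": rec.psm_id,
            "scan_id": rec.scan_id,
            "peptide": rec.peptide_sequence,
            "protein": ";".join(rec.protein_ids),
            "sn_estimated": int(rec.sn_estimated),
        }
        for obs in rec.observations:
            label = obs.channel_label
            row[f"{label}_mz"] = obs.mz_observed if obs.matched else None
            row[f"{label}_intensity"] = obs.intensity if obs.matched else None
            row[f"{label}_noise"] = obs.noise if obs.matched else None
            row[f"{label}_resolution"] = obs.resolution if obs.matched else None
        rows.append(row)
    cols = ["psm_id", "scan_id", "peptide", "protein", "sn_estimated"]
    cols += _channel_columns()
    frame = pd.DataFrame(rows, columns=cols)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8")


def read_psm_table(path) -> list[PsmQuantRecord]:
    """Read PSM records written by :func:`write_psm_table`."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], encoding="utf-8")
    table = reporter_table()
    records = []
    for _, row in frame.iterrows():
        observations = []
        for chan in table:
            mz = row.get(f"{chan.label}_mz")
            if pd.isna(mz):
                observations.append(
                    ReporterObservation(channel_label=chan.label, matched=False)
                )
                continue
            intensity = float(row[f"{chan.label}_intensity"])
            noise_val = row.get(f"{chan.label}_noise")
            noise = None if pd.isna(noise_val) else float(noise_val)
            res_val = row.get(f"{chan.label}_resolution")
            resolution = None if pd.isna(res_val) else float(res_val)
            sn = intensity / noise if noise else 0.0
            observations.append(
                ReporterObservation(
                    channel_label=chan.label,
                    matched=True,
                    mz_observed=float(mz),
                    delta_mz=float(mz) - chan.exact_mz,
                    intensity=intensity,
                    noise=noise,
                    sn=sn,
                    resolution=resolution,
                )
            )
        records.append(
            PsmQuantRecord(
                psm_id=str(row["psm_id"]),
                scan_id=str(row["scan_id"]),
                peptide_sequence=str(row["peptide"]),
                protein_ids=tuple(str(row["protein"]).split(";")),
                observations=tuple(observations),
                sn_estimated=bool(row.get("sn_estimated", 0)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Scan input: mzML via pyteomics, or a plain TSV peak list.

def read_mzml_scans(path, ms_level: int = 2) -> list[Ms2Scan]:
    """Read centroided scans of the given MS level from an mzML file.

    Uses pyteomics when its mzML backend is fully available, otherwise a
    minimal built-in reader covering centroid m/z + intensity arrays
    (64/32-bit floats, zlib or no compression).  Standard mzML carries
    no per-peak noise or resolution; S/N must then be estimated via
    ``default_noise`` at matching time.
    """
    try:
        from pyteomics import mzml as _mzml

        scans = []
        with _mzml.MzML(str(path)) as reader:
            for spectrum in reader:
                if spectrum.get("ms level") != ms_level:
                    continue
                peaks = [
                    Peak(mz=float(mz), intensity=float(inten))
                    for mz, inten in zip(
                        spectrum["m/z array"], spectrum["intensity array"]
                    )
                    if inten > 0
                ]
                scans.append(Ms2Scan(scan_id=str(spectrum["id"]), peaks=peaks))
        return scans
    except Exception as exc:
        # pyteomics' mzML backend has an optional dependency (psims); fall
        # back to the built-in reader only when that backend is unusable
        if not isinstance(exc, ImportError) and "psims" not in str(exc):
            raise
    return _read_mzml_minimal(path, ms_level)


def _read_mzml_minimal(path, ms_level: int) -> list[Ms2Scan]:
    """Minimal namespace-agnostic mzML reader for centroid peak lists."""
    import base64
    import struct
    import zlib
    import xml.etree.ElementTree as ET

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    scans = []
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if local(elem.tag) != "spectrum":
            continue
        level = None
        arrays: dict[str, list[float]] = {}
        for node in elem.iter():
            if local(node.tag) == "cvParam" and node.get("accession") == "MS:1000511":
                level = int(node.get("value"))
        for bda in elem.iter():
            if local(bda.tag) != "binaryDataArray":
                continue
            kind = None
            fmt = "d"
            compressed = False
            payload = None
            for node in bda.iter():
                tag = local(node.tag)
                if tag == "cvParam":
                    acc = node.get("accession")
                    if acc == "MS:1000514":
                        kind = "mz"
                    elif acc == "MS:1000515":
                        kind = "intensity"
                    elif acc == "MS:1000521":
                        fmt = "f"
                    elif acc == "MS:1000574":
                        compressed = True
                elif tag == "binary":
                    payload = node.text or ""
            if kind is None or payload is None:
                continue
            raw = base64.b64decode(payload)
            if compressed:
                raw = zlib.decompress(raw)
            count = len(raw) // struct.calcsize(fmt)
            arrays[kind] = list(struct.unpack(f"<{count}{fmt}", raw))
        if level == ms_level and "mz" in arrays and "intensity" in arrays:
            peaks = [
                Peak(mz=float(mz), intensity=float(inten))
                for mz, inten in zip(arrays["mz"], arrays["intensity"])
                if inten > 0
            ]
            scans.append(Ms2Scan(scan_id=str(elem.get("id")), peaks=peaks))
        elem.clear()
    return scans


def write_scan_tsv(scans: Sequence[Ms2Scan], path) -> None:
    """Write scans as a long TSV: scan_id, mz, intensity, noise, resolution."""
    rows = []
    for scan in scans:
        for p in scan.peaks:
            rows.append(
                {
                    "scan_id": scan.scan_id,
                    "mz": p.mz,
                    "intensity": p.intensity,
                    "noise": p.noise,
                    "resolution": p.resolution,
                }
            )
    pd.DataFrame(
        rows, columns=["scan_id", "mz", "intensity", "noise", "resolution"]
    ).to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8")


def read_scan_tsv(path) -> list[Ms2Scan]:
    """Read scans from the long TSV written by :func:`write_scan_tsv`."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], encoding="utf-8")
    scans = []
    for scan_id, group in frame.groupby("scan_id", sort=False):
        peaks = [
            Peak(
                mz=float(r.mz),
                intensity=float(r.intensity),
                noise=None if pd.isna(r.noise) else float(r.noise),
                resolution=None if pd.isna(r.resolution) else float(r.resolution),
            )
            for r in group.itertuples()
        ]
        scans.append(Ms2Scan(scan_id=str(scan_id), peaks=peaks))
    return scans
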