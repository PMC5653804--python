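"""Dose-volume histograms: data model, CSV I/O and dosimetric metrics.

A DVH describes how an organ's volume is distributed over absorbed dose.
Two equivalent representations are supported:

* **cumulative** — ``V(x)``, the percent of the organ volume receiving at
  least ``x`` Gy; non-increasing with ``V(0) = 100``.
* **differential** — percent of the organ volume falling in each dose bin;
  non-negative, summing to 100.

Internally a DVH stores its bin edges (``nbins + 1`` strictly increasing
doses starting at 0 Gy) plus either cumulative values at the edges or
differential values per bin.  All dosimetric metrics (mean dose, V_x) are
derived from these, so the two forms round-trip exactly.

The file format is a TPS-neutral long-format CSV with the header
``organ,mode,dose_Gy,volume``.  For cumulative curves each row gives
``V(dose)``; for differential curves each row gives the volume in the bin
ending at ``dose`` (the first bin starts at 0 Gy).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DVH",
    "DVHParseError",
    "read_dvh_file",
    "write_dvh_file",
    "to_cumulative",
    "to_differential",
    "v_at",
    "mean_dose",
    "dosimetric_vector",
    "DEFAULT_THRESHOLDS",
]

#: Default V_x thresholds in Gy (5, 10, ..., 50) used for the candidate
#: dosimetric risk-factor set alongside the mean dose.
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(float(x) for x in range(5, 55, 5))

_MODES = ("cumulative", "differential")


class DVHParseError(ValueError):
    """Raised when a DVH file violates the documented layout or invariants."""


@dataclass
class DVH:
    """One organ's dose-volume curve.

    Parameters
    ----------
    organ:
        Organ label, e.g. ``"ipsilateral_lung"``.
    mode:
        ``"cumulative"`` or ``"differential"``.
    bin_edges:
        Strictly increasing dose values in Gy starting at 0.  Length is
        ``nbins + 1``.
    values:
        Volume in percent of organ volume.  Cumulative: one value per edge
        (``V(edge)``).  Differential: one value per bin.
    total_volume_cc:
        Optional absolute organ volume; never required by downstream math.
    """

    organ: str
    mode: str
    bin_edges: np.ndarray
    values: np.ndarray
    total_volume_cc: float | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        e, v = self.bin_edges, self.values
        if self.mode not in _MODES:
            raise ValueError(f"unknown DVH mode {self.mode!r}")
        if e.ndim != 1 or e.size < 2:
            raise ValueError("bin_edges must hold at least two doses")
        if e[0] != 0.0:
            raise ValueError("bin_edges must start at 0 Gy")
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.mode == "cumulative":
            if v.size != e.size:
                raise ValueError("cumulative DVH needs one value per edge")
            if abs(v[0] - 100.0) > 1e-6:
                raise ValueError("cumulative DVH must equal 100% at dose 0")
            if np.any(np.diff(v) > 1e-9):
                raise ValueError("cumulative DVH must be non-increasing")
            if np.any(v < -1e-9):
                raise ValueError("volumes must be non-negative")
        else:
            if v.size != e.size - 1:
                raise ValueError("differential DVH needs one value per bin")
            if np.any(v < -1e-9):
                raise ValueError("differential volumes must be non-negative")
            if abs(v.sum() - 100.0) > 1e-6:
                raise ValueError(
                    f"differential volumes must sum to 100% (got {v.sum():.8f})"
                )

    @property
    def nbins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def max_dose(self) -> float:
        return float(self.bin_edges[-1])


# ---------------------------------------------------------------------------
# representation conversion
# ---------------------------------------------------------------------------

def to_cumulative(d: DVH) -> DVH:
    """Return the cumulative form of *d* on the same bin edges.

    Idempotent on cumulative input.  ``V(edge_j)`` is the total volume in
    bins at or above ``edge_j``; the curve is anchored at ``V(0) = 100`` and
    ``V(max dose) = 0``.
    """
    if d.mode == "cumulative":
        return d
    # reverse cumulative sum of bin volumes; V at last edge is 0
    tail = np.concatenate([np.cumsum(d.values[::-1])[::-1], [0.0]])
    tail[0] = 100.0  # exact anchor against float round-off
    return DVH(d.organ, "cumulative", d.bin_edges.copy(), tail, d.total_volume_cc)


def to_differential(d: DVH) -> DVH:
    """Return the differential form of *d* (bin volumes) on the same edges."""
    if d.mode == "differential":
        return d
    v = -np.diff(d.values)
    # residual volume beyond the last edge is forced to 0 by the invariant
    v = np.clip(v, 0.0, None)
    return DVH(d.organ, "differential", d.bin_edges.copy(), v, d.total_volume_cc)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def v_at(d: DVH, x: float) -> float:
    """Percent of the organ volume receiving at least *x* Gy.

    Linear interpolation of the cumulative curve; doses beyond the last bin
    edge return 0.
    """
    if x < 0:
        raise ValueError("dose threshold must be non-negative")
    c = to_cumulative(d)
    return float(np.interp(x, c.bin_edges, c.values, right=0.0))


def mean_dose(d: DVH) -> float:
    """Mean organ dose in Gy: volume-weighted bin-midpoint average."""
    dd = to_differential(d)
    if dd.values.sum() <= 0:
        raise ValueError("empty DVH has no mean dose")
    mid = 0.5 * (dd.bin_edges[:-1] + dd.bin_edges[1:])
    return float(np.sum(mid * dd.values) / np.sum(dd.values))


def dosimetric_vector(
    d: DVH,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    prefix: str = "V",
) -> dict[str, float]:
    """Mean dose plus V_x for each threshold, as an ordered mapping.

    Keys are ``"MD"`` then ``f"{prefix}{x:g}"``.  Thresholds must be
    strictly increasing; the resulting V_x values are non-increasing.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.size and np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    out: dict[str, float] = {"MD": mean_dose(d)}
    c = to_cumulative(d)
    for x in thr:
        out[f"{prefix}{x:g}"] = float(np.interp(x, c.bin_edges, c.values, right=0.0))
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_HEADER = ["organ", "mode", "dose_Gy", "volume"]


def read_dvh_file(stream) -> list[DVH]:
    """Parse a long-format DVH CSV into one :class:`DVH` per organ.

    The stream (or path) must carry the header ``organ,mode,dose_Gy,volume``
    and rows grouped by organ with strictly increasing dose.  Violations of
    the DVH invariants raise :class:`DVHParseError` naming the row.
    """
    close = False
    if isinstance(stream, (str, bytes)):
        stream = open(stream, "r", newline="")
        close = True
    try:
        reader = csv.reader(stream)
        try:
            header = next(reader)
        except StopIteration:
            raise DVHParseError("empty DVH file") from None
        if [h.strip() for h in header] != _HEADER:
            raise DVHParseError(
                f"malformed header {header!r}; expected {','.join(_HEADER)}"
            )
        groups: dict[str, dict] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise DVHParseError(f"row {lineno}: expected 4 fields, got {len(row)}")
            organ, mode, dose_s, vol_s = (c.strip() for c in row)
            if mode not in _MODES:
                raise DVHParseError(f"row {lineno}: unknown mode {mode!r}")
            try:
                dose, vol = float(dose_s), float(vol_s)
            except ValueError:
                raise DVHParseError(f"row {lineno}: non-numeric dose or volume") from None
            if vol < 0:
                raise DVHParseError(f"row {lineno}: negative volume {vol}")
            g = groups.setdefault(organ, {"mode": mode, "dose": [], "vol": []})
            if g["mode"] != mode:
                raise DVHParseError(f"row {lineno}: mixed modes for organ {organ!r}")
            if g["dose"] and dose <= g["dose"][-1]:
                raise DVHParseError(f"row {lineno}: dose not strictly increasing")
            if (
                mode == "cumulative"
                and g["vol"]
                and vol > g["vol"][-1] + 1e-9
            ):
                raise DVHParseError(
                    f"row {lineno}: cumulative volume increases with dose"
                )
            g["dose"].append(dose)
            g["vol"].append(vol)
        out = []
        for organ, g in groups.items():
            dose = np.asarray(g["dose"])
            vol = np.asarray(g["vol"])
            try:
                if g["mode"] == "cumulative":
                    if dose[0] != 0.0:
                        dose = np.concatenate([[0.0], dose])
                        vol = np.concatenate([[100.0], vol])
                    out.append(DVH(organ, "cumulative", dose, vol))
                else:
                    edges = np.concatenate([[0.0], dose])
                    out.append(DVH(organ, "differential", edges, vol))
            except ValueError as exc:
                raise DVHParseError(f"organ {organ!r}: {exc}") from exc
        return out
    finally:
        if close:
            stream.close()


def write_dvh_file(stream, dvhs: list[DVH]) -> None:
    """Write DVHs in the same long-format CSV dialect, at full precision."""
    close = False
    if isinstance(stream, (str, bytes)):
        stream = open(stream, "w", newline="")
        close = True
    try:
        w = csv.writer(stream)
        w.writerow(_HEADER)
        for d in dvhs:
            if d.mode == "cumulative":
                doses, vols = d.bin_edges, d.values
            else:
                doses, vols = d.bin_edges[1:], d.values
            for dose, vol in zip(doses, vols):
                w.writerow([d.organ, d.mode, repr(float(dose)), repr(float(vol))])
    finally:
        if close:
            stream.close()


def dvhs_to_csv_string(dvhs: list[DVH]) -> str:
    buf = io.StringIO()
    write_dvh_file(buf, dvhs)
    return buf.getvalue()
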