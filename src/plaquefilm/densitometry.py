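"""Net optical density (netOD) and its propagated standard deviation.

In reflection-mode film densitometry the dose-sensitive signal is the
net optical density

    netOD = log10( (P0 - Pbg) / (P - Pbg) )

where ``P0`` and ``P`` are the mean red-channel pixel values of the same
film region before and after irradiation and ``Pbg`` is the scanner
background (zero-reflectance) signal.  With this orientation netOD
increases as the film darkens, i.e. with dose.

The per-film netOD is re-zeroed against an unirradiated control film
(``delta_net_od``), anchoring the dose-response curve at (0 Gy, 0).

The standard deviation of netOD follows from first-order propagation of
the pixel-value SDs:

    SD(netOD) = (1/ln 10) * sqrt( SD(P0)^2/(P0-Pbg)^2 + SD(P)^2/(P-Pbg)^2 )
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from plaquefilm.scan_io import RoiStat

LN10 = math.log(10.0)


@dataclass(frozen=True)
class FilmReading:
    """Paired pre/post-irradiation pixel statistics for one film region.

    ``sd_p0`` and ``sd_p`` are the pixel-value SDs of the ROI (not the
    standard errors of the mean); see :func:`sd_net_od`.
    """

    p0: float
    p: float
    p_bg: float = 0.0
    sd_p0: float = 0.0
    sd_p: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd_p0 < 0 or self.sd_p < 0:
            raise ValueError("pixel-value SDs must be >= 0")
        if self.p0 <= self.p_bg or self.p <= self.p_bg:
            raise ValueError("background exceeds signal: require p0 > p_bg and p > p_bg")


@dataclass(frozen=True)
class NetOD:
    """A net optical density with its propagated SD (both dimensionless)."""

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def net_od(r: FilmReading) -> float:
    """netOD = log10((p0 - p_bg) / (p - p_bg)); positive when the film darkened."""
    return math.log10((r.p0 - r.p_bg) / (r.p - r.p_bg))


def delta_net_od(net_od_irr: float, net_od_zero: float) -> float:
    """Re-zero a netOD against the unirradiated (0 Gy) control value."""
    if not (math.isfinite(net_od_irr) and math.isfinite(net_od_zero)):
        raise ValueError("netOD values must be finite")
    return net_od_irr - net_od_zero


def sd_net_od(r: FilmReading, standard_error: bool = False, n0: int = 1, n: int = 1) -> float:
    """First-order SD of netOD from the pixel-value SDs.

    With ``standard_error=True`` the ROI SDs are divided by sqrt(n) so
    that the propagated quantity reflects the uncertainty of the ROI
    *means* rather than the pixel scatter.
    """
    s0 = r.sd_p0 / math.sqrt(n0) if standard_error else r.sd_p0
    s1 = r.sd_p / math.sqrt(n) if standard_error else r.sd_p
    return (1.0 / LN10) * math.sqrt(s0**2 / (r.p0 - r.p_bg) ** 2 + s1**2 / (r.p - r.p_bg) ** 2)


def netod_with_sd(r: FilmReading, **kwargs) -> NetOD:
    """Convenience bundle of :func:`net_od` and :func:`sd_net_od`."""
    return NetOD(value=net_od(r), sd=sd_net_od(r, **kwargs))


def reading_from_rois(pre: RoiStat, post: RoiStat, p_bg: float = 0.0, label: str = "") -> FilmReading:
    """Build a FilmReading from pre/post ROI statistics of the same region."""
    return FilmReading(p0=pre.mean_pv, p=post.mean_pv, p_bg=p_bg, sd_p0=pre.sd_pv, sd_p=post.sd_pv, label=label)


def read_readings_table(path: str | Path) -> list[FilmReading]:
    """Read film readings from CSV with columns label, p0, sd_p0, p, sd_p, p_bg."""
    df = pd.read_csv(path)
    required = {"p0", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"readings table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            FilmReading(
                p0=float(row["p0"]),
                p=float(row["p"]),
                p_bg=float(row.get("p_bg", 0.0)),
                sd_p0=float(row.get("sd_p0", 0.0)),
                sd_p=float(row.get("sd_p", 0.0)),
                label=str(row.get("label", "")),
            )
        )
    return out
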