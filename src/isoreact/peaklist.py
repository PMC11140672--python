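"""Reading, filtering and writing centroided peak lists.

The tool consumes centroided peak lists only (m/z, intensity, signal-to-noise
as delimited text, one file per sample/replicate); peak picking and mass
calibration happen upstream in vendor software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .chem import format_formula, monoisotopic_mass, mz_deprotonated

logger = logging.getLogger(__name__)

__all__ = ["Peak", "PeakList", "read_peaklist", "filter_peaks",
           "write_peaklist", "write_reconstructed_spectrum"]

# Column-name aliases accepted on input (lowercased, stripped).
_COLUMN_ALIASES = {
    "mz": ("mz", "m/z", "mass", "m_z"),
    "intensity": ("intensity", "i", "abundance", "int"),
    "s2n": ("s2n", "sn", "snr", "s/n", "signal_to_noise", "signal-to-noise"),
}


@dataclass(frozen=True)
class Peak:
    """A centroided peak: m/z (Th, z = 1), intensity and signal-to-noise."""

    mz: float
    intensity: float
    s2n: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z {self.mz}")
        if self.intensity < 0 or self.s2n < 0:
            raise ValueError("negative intensity or s2n")


@dataclass(frozen=True)
class PeakList:
    """A sorted centroided peak list with sample metadata.

    Peaks are stored ascending by m/z; peaks closer than ``merge_tol_ppm``
    are merged on construction (intensity-weighted m/z, summed intensity,
    maximum s2n).
    """

    peaks: tuple[Peak, ...]
    sample_id: str = ""
    timepoint_days: float | None = None
    replicate: int | None = None
    role: str = "reaction"  # "reaction" | "control"
    merge_tol_ppm: float = 0.1

    def __post_init__(self):
        merged = _sort_and_merge(self.peaks, self.merge_tol_ppm)
        object.__setattr__(self, "peaks", merged)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mz": [p.mz for p in self.peaks],
             "intensity": [p.intensity for p in self.peaks],
             "s2n": [p.s2n for p in self.peaks]}
        )


def _sort_and_merge(peaks: Iterable[Peak], merge_tol_ppm: float) -> tuple[Peak, ...]:
    ordered = sorted(peaks, key=lambda p: p.mz)
    if not ordered:
        return ()
    merged: list[Peak] = [ordered[0]]
    for p in ordered[1:]:
        last = merged[-1]
        if (p.mz - last.mz) / last.mz * 1e6 <= merge_tol_ppm:
            total = last.intensity + p.intensity
            mz = (last.mz * last.intensity + p.mz * p.intensity) / total if total > 0 \
                else (last.mz + p.mz) / 2
            merged[-1] = Peak(mz, total, max(last.s2n, p.s2n))
        else:
            merged.append(p)
    return tuple(merged)


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lookup = {c.strip().lower(): c for c in columns}
    resolved = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lookup:
                resolved[canonical] = lookup[alias]
                break
        else:
            raise ValueError(
                f"missing required column {canonical!r} (accepted aliases: "
                f"{', '.join(aliases)}); found {list(columns)}"
            )
    return resolved


def read_peaklist(path, sep: str | None = None, **metadata) -> PeakList:
    """Read a delimited peak-list file with mz/intensity/s2n columns.

    The delimiter is sniffed when *sep* is None.  Rows that fail numeric
    parsing are skipped and counted in a log message.  Extra keyword
    arguments become :class:`PeakList` metadata.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty:
        raise ValueError(f"empty peak list file: {path}")
    cols = _resolve_columns(df.columns)
    sub = df[[cols["mz"], cols["intensity"], cols["s2n"]]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = sub.isna().any(axis=1)
    if bad.any():
        logger.warning("%s: skipped %d unparseable row(s)", path, int(bad.sum()))
    sub = sub[~bad]
    peaks = [Peak(float(m), float(i), float(s)) for m, i, s in sub.itertuples(index=False)]
    pl = PeakList(tuple(peaks), **metadata)
    logger.info("%s: read %d peaks", path, len(pl))
    return pl


def filter_peaks(pl: PeakList, min_s2n: float = 4.0,
                 min_intensity: float = 1e6) -> PeakList:
    """Keep peaks with s2n strictly above *min_s2n* AND intensity strictly
    above *min_intensity* (the picking thresholds of the acquisition:
    s2n > 4, intensity > 10⁶)."""
    if min_s2n < 0 or min_intensity < 0:
        raise ValueError("thresholds must be non-negative")
    kept = tuple(p for p in pl.peaks
                 if p.s2n > min_s2n and p.intensity > min_intensity)
    return replace(pl, peaks=kept)


def write_peaklist(pl: PeakList, path) -> None:
    # 12 significant digits: sub-0.01 ppm m/z round-trip fidelity
    pl.to_frame().to_csv(path, index=False, float_format="%.12g")
    logger.info("%s: wrote %d peaks", path, len(pl))


def write_reconstructed_spectrum(consensus, path, table=None) -> pd.DataFrame:
    """Write a reconstructed consensus spectrum as a CSV table.

    One row per consensus formula: Hill formula, theoretical deprotonated
    m/z, mean intensity across replicates, and intensity relative to the
    most intense formula (max = 1).  Returns the table.
    """
    if not consensus.formulas:
        raise ValueError("empty consensus set")
    rows = []
    for f, inten in consensus.items():
        mz = mz_deprotonated(monoisotopic_mass(f, table))
        rows.append((format_formula(f), mz, inten))
    df = pd.DataFrame(rows, columns=["formula", "theoretical_mz", "mean_intensity"])
    df["relative_intensity"] = df["mean_intensity"] / df["mean_intensity"].max()
    df = df.sort_values("theoretical_mz", kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.9g")
    logger.info("%s: wrote %d consensus formulas", path, len(df))
    return df
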