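"""Sequence-order features from the Hilbert-Huang transform.

Each sequence is encoded as 15 time series — one per dinucleotide
physicochemical property (nearest-neighbour thermodynamics, hydrophilicity,
and base-step geometry), sliding a width-2 window one step at a time so a
length-L sequence yields series of length L-1. Each series is decomposed by
empirical mode decomposition (EMD) into intrinsic mode functions (IMFs), and
Hilbert spectral analysis of each IMF's analytic signal yields instantaneous
amplitude and frequency. Per series, the first 8 IMFs (absent ones
contribute zeros) each emit 4 statistics — mean and variance of
instantaneous amplitude, mean instantaneous frequency (cycles/step), and
energy fraction — for 32 features, hence 15 x 32 = 480 per sequence.

The whole path is deterministic: no randomness anywhere, so repeated
extraction is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert as analytic_signal

from .io_formats import RnaRecord

# --- numerical configuration ------------------------------------------------
SIFT_TOL = 0.2        # Cauchy stop criterion for sifting
MAX_SIFTS = 50        # hard cap on sifting iterations per IMF
MAX_IMFS = 10         # decomposition stops after this many IMFs
IMF_CAP = 8           # IMFs beyond this are folded into the residual's role
N_MIRROR = 2          # extrema mirrored past each boundary for the envelopes
EDGE_TRIM = 5         # samples dropped per side in amplitude statistics
STAT_NAMES = ("amean", "avar", "fmean", "efrac")

PROPERTY_NAMES = (
    "enthalpy", "enthalpy2", "entropy", "entropy2",
    "free_energy", "free_energy2", "hydrophilicity", "hydrophilicity2",
    "rise", "roll", "shift", "slide", "stackingenergy", "tilt", "twist",
)

#: Frozen 480-name layout: property-major, then IMF index, then statistic.
HHT_FEATURE_NAMES: list[str] = [
    f"hht.{prop}.imf{k}.{stat}"
    for prop in PROPERTY_NAMES
    for k in range(1, IMF_CAP + 1)
    for stat in STAT_NAMES
]
assert len(HHT_FEATURE_NAMES) == 480


def load_property_table(path: str | Path | None = None) -> pd.DataFrame:
    """The 16-dinucleotide x 15-property table (package data, overridable).

    Values are curated from the standard RNA nearest-neighbour thermodynamic
    sets and dinucleotide structural-property compilations; the table ships
    with the package so extraction never needs the network.
    """
    if path is None:
        ref = resources.files("stemloop.data") / "dinucleotide_properties.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", index_col="dinucleotide")
    else:
        df = pd.read_csv(path, sep="\t", index_col="dinucleotide")
    missing = set(PROPERTY_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"property table missing columns: {sorted(missing)}")
    if len(df.index) != 16 or df[list(PROPERTY_NAMES)].isna().any().any():
        raise ValueError("property table must cover all 16 dinucleotides")
    return df[list(PROPERTY_NAMES)]


def encode_series(seq: RnaRecord, table: pd.DataFrame) -> dict[str, np.ndarray]:
    """The 15 per-property time series of a sequence (each of length L-1)."""
    dimers = [seq.sequence[i : i + 2] for i in range(len(seq) - 1)]
    try:
        sub = table.loc[dimers]
    except KeyError as exc:
        raise ValueError(f"dinucleotide absent from property table: {exc}") from exc
    return {prop: sub[prop].to_numpy(dtype=float) for prop in PROPERTY_NAMES}


# ---------------------------------------------------------------------------
# Empirical mode decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IMFSet:
    """EMD output: ordered IMFs plus the residual (all of the input length)."""

    imfs: list[np.ndarray]
    residual: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima, plateaus collapsed.

    A plateau counts as a single extremum at its midpoint, judged by the
    signs of the nearest non-zero differences on each side.
    """
    d = np.diff(x)
    maxima: list[int] = []
    minima: list[int] = []
    i = 0
    n = len(d)
    prev_sign = 0
    prev_pos = 0
    while i < n:
        s = np.sign(d[i])
        if s == 0:
            i += 1
            continue
        if prev_sign > 0 and s < 0:
            maxima.append((prev_pos + 1 + i) // 2)
        elif prev_sign < 0 and s > 0:
            minima.append((prev_pos + 1 + i) // 2)
        prev_sign = s
        prev_pos = i
        i += 1
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _mirror_extend(
    idx: np.ndarray, vals: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to N_MIRROR extrema past each end to anchor the splines."""
    left_i = [2 * idx[0] - idx[k] for k in range(1, min(N_MIRROR, len(idx) - 1) + 1)]
    left_v = [vals[k] for k in range(1, min(N_MIRROR, len(idx) - 1) + 1)]
    right_i = [
        2 * idx[-1] - idx[-1 - k]
        for k in range(1, min(N_MIRROR, len(idx) - 1) + 1)
    ]
    right_v = [vals[-1 - k] for k in range(1, min(N_MIRROR, len(idx) - 1) + 1)]
    xs = np.concatenate([left_i[::-1], idx, right_i])
    ys = np.concatenate([left_v[::-1], vals, right_v])
    # mirrored points can coincide when extrema touch the boundary; dedupe
    xs, keep = np.unique(xs, return_index=True)
    return xs, ys[keep]


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    """Mean of the cubic-spline upper and lower envelopes, or None if the
    series lacks two maxima or two minima (sifting cannot proceed)."""
    maxima, minima = _local_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        return None
    t = np.arange(len(x), dtype=float)
    mi, mv = _mirror_extend(maxima, x[maxima], len(x))
    ni, nv = _mirror_extend(minima, x[minima], len(x))
    upper = CubicSpline(mi, mv)(t)
    lower = CubicSpline(ni, nv)(t)
    return (upper + lower) / 2.0


def _is_monotonic(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def emd(
    series: np.ndarray,
    max_imfs: int = MAX_IMFS,
    sift_tol: float = SIFT_TOL,
) -> IMFSet:
    """Empirical mode decomposition by envelope sifting.

    Sifting stops when the Cauchy criterion
    ``SD = sum((h_prev - h)^2) / sum(h_prev^2) < sift_tol`` or after
    MAX_SIFTS passes; decomposition stops when the residual is monotonic,
    lacks enough extrema for envelopes, or ``max_imfs`` is reached. The sum
    of IMFs plus the residual reconstructs the input exactly (the residual
    is defined by subtraction).
    """
    x = np.asarray(series, dtype=float)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imfs and not _is_monotonic(residual):
        h = residual.copy()
        mean = _envelope_mean(h)
        if mean is None:
            break
        for _ in range(MAX_SIFTS):
            h_new = h - mean
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sift_tol:
                break
            mean = _envelope_mean(h)
            if mean is None:
                break
        imfs.append(h)
        residual = residual - h
    return IMFSet(imfs, residual)


# ---------------------------------------------------------------------------
# Hilbert spectral analysis
# ---------------------------------------------------------------------------

def _trim(a: np.ndarray, k: int = EDGE_TRIM) -> np.ndarray:
    """Drop k samples per side (edge-artifact suppression); never empty."""
    return a[k:-k] if len(a) > 2 * k else a


def hilbert_block(imfset: IMFSet, total_energy: float | None = None) -> np.ndarray:
    """32 spectral statistics for one decomposed series.

    For each of the first IMF_CAP IMFs (missing ones contribute zeros):
    mean and variance of instantaneous amplitude (edge-trimmed), mean
    instantaneous frequency from the unwrapped-phase one-sided difference in
    cycles/step (endpoints excluded), and the IMF's share of the input
    signal's energy.
    """
    if total_energy is None:
        total_energy = float(np.sum(imfset.reconstruct() ** 2))
    out = np.zeros(IMF_CAP * len(STAT_NAMES))
    for k, imf in enumerate(imfset.imfs[:IMF_CAP]):
        z = analytic_signal(imf)
        amp = _trim(np.abs(z))
        phase = np.unwrap(np.angle(z))
        freq = np.diff(phase) / (2.0 * np.pi)
        freq_interior = freq[1:-1] if len(freq) > 2 else freq
        efrac = float(np.sum(imf * imf)) / total_energy if total_energy > 0 else 0.0
        out[4 * k : 4 * k + 4] = (
            float(np.mean(amp)),
            float(np.var(amp)),
            float(np.mean(freq_interior)) if len(freq_interior) else 0.0,
            efrac,
        )
    return out


def hht_block(
    seq: RnaRecord, table: pd.DataFrame | None = None
) -> np.ndarray:
    """The full 480-value Hilbert-Huang block, in the frozen name order."""
    if table is None:
        table = load_property_table()
    series_map = encode_series(seq, table)
    blocks = []
    for prop in PROPERTY_NAMES:
        s = series_map[prop]
        imfset = emd(s)
        blocks.append(hilbert_block(imfset, total_energy=float(np.sum(s * s))))
    out = np.concatenate(blocks)
    assert out.shape == (480,)
    return out
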