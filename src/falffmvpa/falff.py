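"""Amplitude of low-frequency fluctuation (ALFF/fALFF) maps.

fALFF summarises how much of a BOLD time series' total fluctuation power
lies in the canonical low-frequency band (0.01-0.08 Hz).  The series is
Fourier-transformed without prior band-pass filtering, the power spectrum
is square-rooted to obtain per-bin amplitudes, and fALFF is the ratio of
summed in-band amplitudes to summed amplitudes over the full spectrum
(DC excluded).  Because it is a ratio, fALFF is invariant to global
scaling of the signal; ALFF (the mean in-band amplitude) is not.

Maps are z-scored within an analysis mask (zfALFF) so values are
comparable across regions, and pre/post sessions are compared on the
voxelwise difference (post - pre), where positive values mean an
increase in spontaneous activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np

__all__ = [
    "LOW_FREQ_BAND",
    "MIN_SERIES_LENGTH",
    "VolumeSeries",
    "FALFFMap",
    "amplitude_spectrum",
    "falff",
    "falff_map",
    "zscore_map",
    "session_difference",
]

#: Canonical low-frequency band for spontaneous BOLD fluctuations, in Hz.
LOW_FREQ_BAND: Tuple[float, float] = (0.01, 0.08)

#: Minimum number of time points for a meaningful spectral estimate.
MIN_SERIES_LENGTH = 32


@dataclass(frozen=True)
class VolumeSeries:
    """A 4D BOLD-like series on a voxel grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        Samples in arbitrary BOLD units.
    dt : float
        Sampling interval (repetition time) in seconds.
    affine : ndarray, shape (4, 4)
        Voxel-index -> MNI mm mapping (RAS).
    n_discarded : int
        Number of initial volumes already removed upstream (dummy scans).
    """

    data: np.ndarray
    dt: float
    affine: np.ndarray
    n_discarded: int = 0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        affine = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "affine", affine)
        if data.ndim != 4:
            raise ValueError(f"expected a 4D array, got shape {data.shape}")
        if data.shape[3] < MIN_SERIES_LENGTH:
            raise ValueError(
                f"time axis has {data.shape[3]} samples; need >= {MIN_SERIES_LENGTH}"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @classmethod
    def from_nifti(cls, path: str | Path, dt: float | None = None,
                   discard: int = 10) -> "VolumeSeries":
        """Load a 4D NIfTI, dropping the first ``discard`` volumes.

        The drop mirrors the standard removal of initial dummy scans.
        ``dt`` overrides the pixdim[4] stored in the header when given.
        """
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4D image, got {data.ndim}D")
        if discard < 0 or discard >= data.shape[3]:
            raise ValueError(f"cannot discard {discard} of {data.shape[3]} volumes")
        if dt is None:
            dt = float(img.header.get_zooms()[3])
        return cls(data[..., discard:], dt=dt, affine=np.asarray(img.affine),
                   n_discarded=discard)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = self.dt
        img.header.set_zooms(zooms)
        nib.save(img, str(path))


@dataclass(frozen=True)
class FALFFMap:
    """A voxelwise map of (z-scored) fALFF values on a 3D grid.

    ``values`` are defined only where ``mask`` is True; everywhere else
    they are NaN.  ``kind`` tracks the processing stage: ``alff``,
    ``falff`` (in [0, 1]), ``zfalff`` (z-scored within mask) or
    ``delta_zfalff`` (post minus pre).
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    kind: str = "falff"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if values.shape != mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.kind not in {"alff", "falff", "zfalff", "delta_zfalff"}:
            raise ValueError(f"unknown map kind {self.kind!r}")
        out = np.where(mask, values, np.nan)
        object.__setattr__(self, "values", out)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    def to_nifti(self, path: str | Path) -> None:
        """Write the map plus a JSON sidecar recording its provenance."""
        import json

        import nibabel as nib

        img = nib.Nifti1Image(
            np.where(self.mask, self.values, 0.0).astype(np.float32), self.affine
        )
        nib.save(img, str(path))
        sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
        meta = {"kind": self.kind, **self.meta}
        Path(f"{sidecar}.json").write_text(json.dumps(meta, indent=2))


def amplitude_spectrum(ts: np.ndarray, dt: float) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of a time series.

    The power spectrum is square-rooted to give per-bin amplitudes,
    normalised so that the summed squared amplitudes equal the signal
    energy ``sum(ts**2)`` (Parseval).  Frequency resolution is
    ``1 / (N * dt)``.

    Returns
    -------
    freqs : ndarray
        Non-negative frequencies in Hz (DC bin included).
    amps : ndarray
        Amplitude (square root of power) per frequency bin.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 1:
        raise ValueError("ts must be 1-dimensional")
    n = ts.shape[0]
    if n < MIN_SERIES_LENGTH:
        raise ValueError(f"series has {n} samples; need >= {MIN_SERIES_LENGTH}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    spec = np.fft.rfft(ts)
    freqs = np.fft.rfftfreq(n, d=dt)
    # One-sided power with Parseval normalisation: interior bins carry the
    # energy of both +f and -f; DC (and Nyquist, for even N) appear once.
    weights = np.full(freqs.shape, 2.0 / n)
    weights[0] = 1.0 / n
    if n % 2 == 0:
        weights[-1] = 1.0 / n
    amps = np.sqrt(weights) * np.abs(spec)
    return freqs, amps


def falff(
    ts: np.ndarray,
    dt: float,
    band: Tuple[float, float] = LOW_FREQ_BAND,
    ratio: str = "sum",
) -> Tuple[float, float]:
    """ALFF and fALFF of a single time series.

    ALFF is the mean amplitude over bins inside ``band`` (closed on both
    ends).  fALFF divides the in-band amplitude by the amplitude over the
    entire spectrum excluding the DC bin, which encodes the signal mean
    rather than fluctuation.  ``ratio='sum'`` uses sum-over-sum (the
    standard definition); ``ratio='mean'`` uses mean-over-mean, which
    differs only by the constant bin-count factor.

    Returns
    -------
    (alff, falff) : tuple of float
        ``falff`` lies in [0, 1].
    """
    if ratio not in {"sum", "mean"}:
        raise ValueError("ratio must be 'sum' or 'mean'")
    freqs, amps = amplitude_spectrum(ts, dt)
    lo, hi = band
    nyquist = 1.0 / (2.0 * dt)
    if not (0.0 < lo < hi < nyquist + 1e-12):
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyquist:.4g})")
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValueError(
            f"band {band} contains no frequency bins at resolution "
            f"{freqs[1] - freqs[0]:.3g} Hz"
        )
    nonzero = freqs > 0
    alff_val = float(amps[in_band].mean())
    if ratio == "sum":
        num, den = amps[in_band].sum(), amps[nonzero].sum()
    else:
        num, den = amps[in_band].mean(), amps[nonzero].mean()
    falff_val = float(num / den) if den > 0 else 0.0
    return alff_val, falff_val


def falff_map(
    series: VolumeSeries,
    band: Tuple[float, float] = LOW_FREQ_BAND,
    mask: np.ndarray | None = None,
    kind: str = "falff",
    ratio: str = "sum",
) -> FALFFMap:
    """Voxelwise ALFF or fALFF over a 4D series.

    ``mask`` restricts computation (default: all voxels).  ``kind``
    selects which statistic populates the map ('alff' or 'falff').
    """
    if kind not in {"alff", "falff"}:
        raise ValueError("kind must be 'alff' or 'falff'")
    if mask is None:
        mask = np.ones(series.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape:
        raise ValueError("mask shape does not match series grid")
    values = np.full(series.shape, np.nan)
    idx = np.argwhere(mask)
    flat = series.data[mask]  # (n_voxels, nt)
    for row, ts in zip(idx, flat):
        a, f = falff(ts, series.dt, band=band, ratio=ratio)
        values[tuple(row)] = a if kind == "alff" else f
    return FALFFMap(values=values, mask=mask, affine=series.affine, kind=kind,
                    meta={"band": list(band), "dt": series.dt,
                          "n_discarded": series.n_discarded, "ratio": ratio})


def zscore_map(m: FALFFMap, mask: np.ndarray | None = None) -> FALFFMap:
    """Z-score a map within an analysis mask.

    The mask defaults to the map's own validity mask; a grey-matter
    submask changes every z-value because the reference mean/SD change.
    """
    if mask is None:
        mask = m.mask
    mask = np.asarray(mask, dtype=bool) & m.mask
    if mask.sum() < 2:
        raise ValueError("z-scoring mask must contain at least 2 voxels")
    vals = m.values[mask]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite map values inside mask")
    sd = vals.std()
    if sd == 0:
        raise ValueError("zero variance inside mask; z-scores undefined")
    z = (m.values - vals.mean()) / sd
    return FALFFMap(values=z, mask=mask, affine=m.affine, kind="zfalff",
                    meta=dict(m.meta))


def session_difference(post: FALFFMap, pre: FALFFMap) -> FALFFMap:
    """Voxelwise post-minus-pre difference of two zfALFF maps.

    Positive values embody an increase in spontaneous activity over the
    treatment period.
    """
    if post.kind != "zfalff" or pre.kind != "zfalff":
        raise ValueError("session_difference expects zfalff maps")
    if post.values.shape != pre.values.shape:
        raise ValueError("session grids differ")
    if not np.array_equal(post.mask, pre.mask):
        raise ValueError("session masks differ")
    return FALFFMap(values=post.values - pre.values, mask=post.mask,
                    affine=post.affine, kind="delta_zfalff", meta=dict(post.meta))
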