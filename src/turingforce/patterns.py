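"""Classify field snapshots into pattern regimes and measure wavenumbers.

The observables mirror what is read off experimental and simulated
images: whether the field is spatially structured (spatial standard
deviation), whether it moves in time (temporal standard deviation at
fixed probe points), the dominant radial wavenumber of the structure
(annulus-integrated 2-D power spectrum), and the planform (hexagonal
spot lattices are asymmetric about the field mean, so the skewness of
the amplitude distribution separates spots from stripes; stripes
concentrate spectral power in a single orientation).

Wavenumbers are quoted in the same units as the linear-stability
modules (radians per dimensionless length) and compared in units of the
spectral bin 2*pi/L imposed by the periodic domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PatternReport", "radial_power_spectrum", "classify",
           "wavelength_locked"]

#: relative homogeneity thresholds (fraction of the field amplitude scale)
EPS_SPATIAL = 1e-3
EPS_TEMPORAL = 1e-3
#: |skewness| above this marks a hexagonal (spot) planform
SKEW_SPOTS = 0.3
#: angular spectral concentration above this marks a single-orientation
#: (stripe) planform
ANGULAR_STRIPES = 0.6
#: dominant-annulus power below this fraction of total structured power
#: falls through to the irregular bucket
PEAK_FRACTION_MIN = 0.15

LABELS = ("homogeneous-steady", "homogeneous-oscillatory", "spots",
          "stripes", "mixed", "irregular")


@dataclass(frozen=True)
class PatternReport:
    label: str
    dominant_k: float
    spatial_sd: float
    temporal_sd: float
    skewness: float
    k_bin: float
    angular_concentration: float = float("nan")

    @property
    def is_patterned(self) -> bool:
        return self.label in ("spots", "stripes", "mixed", "irregular")


def _as_field(obj) -> np.ndarray:
    u = getattr(obj, "u", obj)
    return np.asarray(u, dtype=float)


def radial_power_spectrum(field: np.ndarray, dx: float):
    """Annulus-integrated power of the 2-D DFT of a mean-removed field.

    Returns (k bin centers, power per bin); bins have width 2*pi/L with
    L the longer domain side, starting at k=0 (the k=0 bin holds only
    the residual mean and is zero after mean removal).
    """
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    ny, nx = field.shape
    L = dx * max(nx, ny)
    f = field - field.mean()
    F = np.fft.fft2(f)
    power = np.abs(F) ** 2
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=dx)
    kmag = np.hypot(*np.meshgrid(kx, ky))
    dk = 2.0 * np.pi / L
    nbins = int(np.ceil(kmag.max() / dk)) + 1
    idx = np.minimum((kmag / dk + 0.5).astype(int), nbins - 1)
    pk = np.bincount(idx.ravel(), weights=power.ravel(), minlength=nbins)
    k_centers = dk * np.arange(nbins)
    return k_centers, pk


def _angular_concentration(field: np.ndarray, dx: float, k_dom: float,
                           dk: float, nbins_theta: int = 12) -> float:
    """Fraction of dominant-annulus power in the most-populated
    orientation bin (angles folded mod pi)."""
    ny, nx = field.shape
    f = field - field.mean()
    F = np.fft.fft2(f)
    power = np.abs(F) ** 2
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=dx)
    KX, KY = np.meshgrid(kx, ky)
    kmag = np.hypot(KX, KY)
    ring = np.abs(kmag - k_dom) <= 0.75 * dk
    if not np.any(ring):
        return float("nan")
    theta = np.mod(np.arctan2(KY[ring], KX[ring]), np.pi)
    w = power[ring]
    hist, _ = np.histogram(theta, bins=nbins_theta, range=(0.0, np.pi),
                           weights=w)
    total = hist.sum()
    return float(hist.max() / total) if total > 0 else float("nan")


def _probe_points(shape: tuple[int, int], n: int = 4):
    ny, nx = shape
    iy = (np.arange(n) * ny) // n + ny // (2 * n)
    ix = (np.arange(n) * nx) // n + nx // (2 * n)
    return np.meshgrid(iy, ix, indexing="ij")


def classify(snapshots, dx: float) -> PatternReport:
    """Label a time-ordered snapshot sequence.

    Homogeneous states (spatial sd below threshold) split into steady
    vs oscillatory by the temporal sd at 16 fixed probe points across
    the sequence; structured states split into spots / stripes / mixed
    by the skewness and angular-concentration rules, with irregular as
    the fallback for weak or broad spectra.  Snapshots may be
    FieldState objects or bare 2-D arrays; the activator field is
    classified.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least 2 snapshots to classify")
    fields = [_as_field(s) for s in snapshots]
    last = fields[-1]
    iy, ix = _probe_points(last.shape)
    probe_series = np.stack([f[iy, ix] for f in fields])
    temporal_sd = float(np.mean(np.std(probe_series, axis=0)))
    spatial_sd = float(np.std(last))
    scale = max(1.0, abs(float(np.mean(last))))
    k, pk = radial_power_spectrum(last, dx)
    dk = k[1] - k[0] if len(k) > 1 else float("nan")

    if spatial_sd < EPS_SPATIAL * scale:
        label = ("homogeneous-oscillatory"
                 if temporal_sd >= EPS_TEMPORAL * scale
                 else "homogeneous-steady")
        return PatternReport(label=label, dominant_k=0.0,
                             spatial_sd=spatial_sd, temporal_sd=temporal_sd,
                             skewness=0.0, k_bin=dk)
    skew = float(stats.skew(last.ravel()))

    structured = pk[1:]
    i_dom = int(np.argmax(structured)) + 1
    k_dom = float(k[i_dom])
    peak_fraction = float(structured[i_dom - 1] / structured.sum())
    if peak_fraction < PEAK_FRACTION_MIN:
        return PatternReport(label="irregular", dominant_k=k_dom,
                             spatial_sd=spatial_sd, temporal_sd=temporal_sd,
                             skewness=skew, k_bin=dk)
    if abs(skew) > SKEW_SPOTS:
        label = "spots"
        conc = float("nan")
    else:
        conc = _angular_concentration(last, dx, k_dom, dk)
        label = "stripes" if conc > ANGULAR_STRIPES else "mixed"
    return PatternReport(label=label, dominant_k=k_dom,
                         spatial_sd=spatial_sd, temporal_sd=temporal_sd,
                         skewness=skew, k_bin=dk,
                         angular_concentration=conc)


def wavelength_locked(before: PatternReport, during: PatternReport,
                      after: PatternReport, tol_bins: int = 1) -> bool:
    """True when the dominant wavenumber survives the forcing episode.

    All three reports must be patterned (locking is undefined for
    homogeneous states); agreement is judged in units of the spectral
    bin width, respecting the domain's wavenumber quantization.
    """
    reports = (before, during, after)
    for r in reports:
        if not r.is_patterned:
            raise ValueError(
                f"wavelength locking undefined for label {r.label!r}")
    dk = max(r.k_bin for r in reports)
    ks = [r.dominant_k for r in reports]
    return (max(ks) - min(ks)) <= tol_bins * dk + 1e-9
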