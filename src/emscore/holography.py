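"""Off-axis hologram reconstruction for quantitative phase imaging.

The reconstruction chain is the numerical half of a telecentric digital
holographic microscope: propagate the recorded interferogram with a Fresnel
transfer function, demodulate the +1 diffraction order carrying the complex
object wave, unwrap the phase, cancel residual tilt and quadratic (defocus)
aberrations with an SVD-based surface fit, and convert optical phase to
geometric height through an assumed cell/medium refractive-index mismatch.

Conventions
-----------
* Grids are indexed ``(row, col)``; spatial frequencies are in cycles/pixel
  unless a pixel pitch converts them to cycles/μm.
* Aberration polynomials are evaluated on integer pixel coordinates centered
  at ``(n_rows // 2, n_cols // 2)``; tilt coefficients are rad/px and
  quadratic coefficients rad/px².
* FFTs use the ``"ortho"`` normalization so propagation conserves power.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2
from scipy import ndimage
from skimage.restoration import unwrap_phase as _unwrap_2d

from .exceptions import DemodulationError

logger = logging.getLogger(__name__)

#: Default He-Ne illumination wavelength (nm).
WAVELENGTH_NM = 632.0
#: Default lateral pixel pitch of the reconstruction (μm).
PIXEL_PITCH_UM = 0.18
#: Default refractive-index mismatch between cell and medium: 1.381 - 1.337.
DELTA_N = 0.044


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Hologram:
    """Recorded off-axis interferogram intensity."""

    intensity: np.ndarray
    pixel_pitch: float = PIXEL_PITCH_UM  # μm
    wavelength: float = WAVELENGTH_NM    # nm

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("hologram intensity must be finite")
        if self.intensity.min() < 0:
            raise ValueError("hologram intensity must be nonnegative")
        if min(self.intensity.shape) < 64:
            raise ValueError("hologram grid must be at least 64x64")


@dataclass
class ComplexField:
    """Complex wavefront sampled on the sensor grid."""

    data: np.ndarray
    pixel_pitch: float = PIXEL_PITCH_UM
    wavelength: float = WAVELENGTH_NM
    distance: float = 0.0  # propagation distance from the recording plane, μm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("complex field must be finite")

    @property
    def power(self) -> float:
        return float(np.sum(np.abs(self.data) ** 2))


@dataclass
class PhaseMap:
    """Unwrapped object phase in radians, background-referenced to zero."""

    phase: np.ndarray
    pixel_pitch: float = PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase map must be finite")


@dataclass
class HeightMap:
    """Geometric height in nm: OPL divided by the index mismatch Δn."""

    height: np.ndarray
    pixel_pitch: float = PIXEL_PITCH_UM
    delta_n: float = DELTA_N

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        if self.delta_n <= 0:
            raise ValueError("delta_n must be positive")


@dataclass
class AberrationModel:
    """Tilt + quadratic phase surface fitted at the sensor plane.

    ``surface(shape)`` evaluates
    ``offset + kx*r + ky*c + qx*r**2 + qy*c**2`` on centered pixel
    coordinates, where ``(kx, ky)`` is :attr:`tilt` and ``(qx, qy)`` is
    :attr:`quadratic`.
    """

    tilt: tuple[float, float]
    quadratic: tuple[float, float]
    offset: float = 0.0
    fit_rms: float = float("nan")

    def surface(self, shape: tuple[int, int]) -> np.ndarray:
        r, c = _centered_coords(shape)
        kx, ky = self.tilt
        qx, qy = self.quadratic
        return self.offset + kx * r + ky * c + qx * r**2 + qy * c**2

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tilt": list(self.tilt),
                    "quadratic": list(self.quadratic),
                    "offset": self.offset,
                    "fit_rms": self.fit_rms,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "AberrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tilt=tuple(d["tilt"]),
            quadratic=tuple(d["quadratic"]),
            offset=d.get("offset", 0.0),
            fit_rms=d.get("fit_rms", float("nan")),
        )


def _centered_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel coordinates centered on (n//2, m//2), as a meshgrid."""
    n, m = shape
    r = np.arange(n, dtype=float) - n // 2
    c = np.arange(m, dtype=float) - m // 2
    return np.meshgrid(r, c, indexing="ij")


# ---------------------------------------------------------------------------
# propagation and demodulation
# ---------------------------------------------------------------------------

def fresnel_reconstruct(holo, distance: float = 0.0) -> ComplexField:
    """Propagate a hologram (or complex field) by the Fresnel transfer function.

    Parameters
    ----------
    holo
        :class:`Hologram`, :class:`ComplexField` or a 2-D array. A hologram's
        real intensity is propagated directly, the classic single-step
        numerical reconstruction of an off-axis hologram.
    distance
        Propagation distance in μm toward the image plane. ``0`` returns the
        input field unchanged (up to FFT round-off).

    The transfer function ``H(f) = exp(-iπλz|f|²)`` has unit modulus, so the
    transform is unitary and conserves total power.
    """
    if isinstance(holo, Hologram):
        u = holo.intensity.astype(complex)
        pitch, wl = holo.pixel_pitch, holo.wavelength
    elif isinstance(holo, ComplexField):
        u, pitch, wl = holo.data, holo.pixel_pitch, holo.wavelength
    else:
        u = np.asarray(holo, dtype=complex)
        pitch, wl = PIXEL_PITCH_UM, WAVELENGTH_NM
    if not np.all(np.isfinite(u)):
        raise ValueError("input field must be finite")

    if distance == 0.0:
        return ComplexField(u.copy(), pitch, wl, 0.0)

    lam_um = wl * 1e-3
    n, m = u.shape
    fr = fftfreq(n, d=pitch)
    fc = fftfreq(m, d=pitch)
    fr2 = fr[:, None] ** 2 + fc[None, :] ** 2
    # Fresnel validity is generous at microscope geometries; log for the record.
    logger.debug("fresnel_reconstruct: z=%g um, lambda=%g um", distance, lam_um)
    h = np.exp(-1j * np.pi * lam_um * distance * fr2)
    out = ifft2(fft2(u, norm="ortho") * h, norm="ortho")
    return ComplexField(out, pitch, wl, distance)


def detect_carrier(holo, min_peak_snr: float = 5.0) -> tuple[int, int]:
    """Locate the +1-order carrier peak as FFT bin indices (row, col)."""
    inten = holo.intensity if isinstance(holo, Hologram) else np.asarray(holo, float)
    n, m = inten.shape
    mag = np.abs(fft2(inten, norm="ortho"))
    fr2d, fc2d = np.meshgrid(fftfreq(n), fftfreq(m), indexing="ij")
    dc_guard = np.hypot(fr2d, fc2d) < 0.04
    search = np.where(dc_guard, 0.0, mag)
    idx = np.unravel_index(np.argmax(search), search.shape)
    floor = np.median(mag[~dc_guard])
    if search[idx] < min_peak_snr * max(floor, 1e-30):
        raise DemodulationError("no off-axis peak above the noise floor")
    return int(idx[0]), int(idx[1])


def isolate_plus_one_order(
    holo,
    carrier: tuple[float, float] | None = None,
    min_peak_snr: float = 5.0,
) -> ComplexField:
    """Demodulate the +1 diffraction order of an off-axis hologram.

    The spectrum is shifted so the carrier peak sits at DC and low-pass
    masked with radius equal to half the carrier offset, which separates the
    +1 order from the DC term for an adequately tilted reference beam.

    Parameters
    ----------
    carrier
        Carrier frequency ``(f_row, f_col)`` in cycles/pixel. ``None``
        selects the strongest spectral peak outside the DC neighbourhood.
    """
    if isinstance(holo, Hologram):
        inten, pitch, wl = holo.intensity, holo.pixel_pitch, holo.wavelength
    else:
        inten = np.asarray(holo, dtype=float)
        pitch, wl = PIXEL_PITCH_UM, WAVELENGTH_NM
    n, m = inten.shape
    spec = fft2(inten, norm="ortho")

    fr = fftfreq(n)
    fc = fftfreq(m)
    fr2d, fc2d = np.meshgrid(fr, fc, indexing="ij")
    rad = np.hypot(fr2d, fc2d)

    if carrier is None:
        idx = detect_carrier(inten, min_peak_snr)
    else:
        # nearest FFT bin to the requested carrier
        ir = int(np.round(carrier[0] * n)) % n
        ic = int(np.round(carrier[1] * m)) % m
        idx = (ir, ic)

    peak_f = np.hypot(fr[idx[0]], fc[idx[1]])
    if peak_f < 0.06:
        warnings.warn(
            "carrier frequency is low; the +1 order may overlap DC",
            stacklevel=2,
        )

    shifted = np.roll(spec, (-idx[0], -idx[1]), axis=(0, 1))
    # raised-cosine apodization over the outer 30% of the pass band keeps
    # ringing around sharp cell edges out of the reconstructed background
    r_cut = peak_f / 2.0
    r_flat = 0.7 * r_cut
    mask = np.clip((r_cut - rad) / (r_cut - r_flat), 0.0, 1.0)
    mask = 0.5 - 0.5 * np.cos(np.pi * mask)
    out = ifft2(shifted * mask, norm="ortho")
    return ComplexField(out, pitch, wl, 0.0)


def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """2-D phase unwrapping (quality-guided, via scikit-image).

    The output is congruent to the input modulo 2π at every pixel.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if not np.all(np.isfinite(wrapped)):
        raise ValueError("wrapped phase must be finite")
    return np.asarray(_unwrap_2d(wrapped), dtype=float)


# ---------------------------------------------------------------------------
# aberration compensation
# ---------------------------------------------------------------------------

def _separable_basis(shape: tuple[int, int], sel=None) -> np.ndarray:
    r, c = _centered_coords(shape)
    cols = [np.ones(shape), r, c, r**2, c**2]
    a = np.stack([col.ravel() for col in cols], axis=1)
    if sel is not None:
        a = a[sel.ravel()]
    return a


def pca_aberration_compensate(
    field: ComplexField,
    residual_threshold: float = 0.1,
    n_refine: int = 2,
    border: int = 12,
) -> tuple[PhaseMap, AberrationModel]:
    """Cancel tilt and quadratic phase aberrations from a demodulated field.

    Procedure: (1) SVD of the unwrapped phase matrix; (2) least-squares fit
    of quadratic polynomials to the two dominant singular-vector pairs;
    (3) synthesis of the aberration surface φ(k,l) from the fitted vectors
    and projection onto the separable tilt+quadratic basis; (4) multiplication
    of the field by exp(-iφ). The tilt/quadratic coefficients are then
    re-estimated on background pixels only (object pixels excluded by a
    residual threshold), which removes the bias the object phase itself would
    otherwise impose on the fit. The background median is subtracted so that
    cell-free pixels sit at phase ≈ 0.
    """
    data = field.data if isinstance(field, ComplexField) else np.asarray(field)
    if min(data.shape) < 64:
        raise ValueError("field must be at least 64x64 for a stable fit")
    psi = unwrap_phase(np.angle(data))
    n, m = psi.shape

    try:
        u_mat, s, vt = np.linalg.svd(psi, full_matrices=False)
    except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate
        raise ValueError("SVD failed on degenerate phase input") from err

    rr = np.arange(n, dtype=float) - n // 2
    cc = np.arange(m, dtype=float) - m // 2
    phi1 = np.zeros_like(psi)
    for i in range(min(2, len(s))):
        if s[i] <= 0:
            continue
        uvec = u_mat[:, i] * np.sqrt(s[i])
        vvec = vt[i] * np.sqrt(s[i])
        pu = np.polynomial.Polynomial.fit(rr, uvec, 2).convert()
        pv = np.polynomial.Polynomial.fit(cc, vvec, 2).convert()
        phi1 += np.outer(pu(rr), pv(cc))

    # project the SVD-synthesized surface onto the tilt+quadratic basis
    basis = _separable_basis(psi.shape)
    coef, *_ = np.linalg.lstsq(basis, phi1.ravel(), rcond=None)

    # Refine on background pixels. Two exclusions matter: the object (a
    # positive phase bump, dilated so its dome tail stays out of the fit)
    # and a border ring, where band-limiting the quadratic chirp during
    # demodulation distorts the phase exactly where the x² leverage peaks.
    border = min(border, n // 8, m // 8)
    keep = np.zeros_like(psi, dtype=bool)
    keep[border:n - border, border:m - border] = True
    bg = keep.copy()
    for _ in range(n_refine):
        resid = psi - (basis @ coef).reshape(psi.shape)
        resid -= np.median(resid[bg]) if bg.any() else 0.0
        obj = ndimage.binary_dilation(resid >= residual_threshold, iterations=8)
        bg = keep & ~obj
        if bg.sum() < 6:  # not enough background to fit; keep current fit
            bg = np.ones_like(psi, dtype=bool)
            break
        coef, *_ = np.linalg.lstsq(
            _separable_basis(psi.shape, bg), psi[bg], rcond=None
        )

    surf = (basis @ coef).reshape(psi.shape)
    resid = psi - surf
    fit_rms = float(np.sqrt(np.mean(resid[bg] ** 2))) if bg.any() else float("nan")
    if fit_rms > 0.1:
        warnings.warn(
            f"aberration fit residual RMS {fit_rms:.3f} rad exceeds 0.1",
            stacklevel=2,
        )

    compensated = unwrap_phase(np.angle(data * np.exp(-1j * surf)))
    compensated -= np.median(compensated[bg])
    # the border ring is corrupted by circular convolution during band-pass
    # demodulation; report it at the background level
    if border > 0:
        compensated[~keep] = 0.0

    model = AberrationModel(
        tilt=(float(coef[1]), float(coef[2])),
        quadratic=(float(coef[3]), float(coef[4])),
        offset=float(coef[0]),
        fit_rms=fit_rms,
    )
    pitch = field.pixel_pitch if isinstance(field, ComplexField) else PIXEL_PITCH_UM
    return PhaseMap(compensated, pitch), model


def phase_to_height(
    phase: PhaseMap | np.ndarray,
    wavelength: float = WAVELENGTH_NM,
    delta_n: float = DELTA_N,
) -> HeightMap:
    """Convert unwrapped phase (rad) to geometric height (nm).

    ``height = (phase · λ / 2π) / Δn``: the optical pathlength divided by the
    cell/medium refractive-index mismatch (default Δn = 1.381 − 1.337 = 0.044).
    """
    if delta_n <= 0:
        raise ValueError("delta_n must be positive")
    if isinstance(phase, PhaseMap):
        arr, pitch = phase.phase, phase.pixel_pitch
    else:
        arr, pitch = np.asarray(phase, dtype=float), PIXEL_PITCH_UM
    height = arr * wavelength / (2.0 * np.pi) / delta_n
    return HeightMap(height, pitch, delta_n)
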