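"""Motion stabilization of frame stacks.

The sharpest frame of the sequence (variance-of-Laplacian focus measure)
is selected as the reference and every other frame is registered to it
with a rigid transform (translation + in-plane rotation) estimated by
Fourier-domain cross-correlation: rotation from the correlation of
polar-resampled spectral magnitudes, translation from sub-pixel phase
cross-correlation.  Eye and camera motion at slit-lamp magnification is
dominantly rigid, so no deformable model is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import warp_polar

from .video_io import FrameStack

__all__ = ["RegistrationResult", "sharpness_score", "select_reference", "register_stack"]

log = logging.getLogger(__name__)


@dataclass
class RegistrationResult:
    """Per-frame rigid transforms mapping each frame onto the reference.

    ``transforms[i] = (dx, dy, rot_deg)``: the shift in pixels (x = column,
    y = row) and rotation in degrees applied to frame *i*. The reference
    frame's transform is the identity. ``residuals[i]`` is the RMS
    intensity difference to the reference after alignment; ``failed``
    flags frames passed through untransformed.
    """

    reference_index: int
    transforms: List[Tuple[float, float, float]]
    residuals: np.ndarray
    failed: List[int] = field(default_factory=list)


def sharpness_score(frame: np.ndarray) -> float:
    """Variance of the Laplacian: a standard focus measure.

    Zero for a constant frame; strictly decreases under Gaussian blur of
    non-constant content.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    return float(np.var(ndimage.laplace(frame)))


def select_reference(stack: FrameStack) -> int:
    """Index of the sharpest frame; ties broken by lowest index."""
    scores = [sharpness_score(f) for f in stack.frames]
    return int(np.argmax(scores))


def _estimate_rotation(ref_spec: np.ndarray, frame: np.ndarray, radius: int) -> float:
    """Rotation (degrees) between frames from polar-warped FFT magnitudes.

    The FFT magnitude is translation-invariant, so rotation decouples
    from shift; the angular offset is found by phase correlation along
    the angle axis of the polar-resampled spectrum.
    """
    spec = _log_spectrum(frame)
    polar_ref = warp_polar(ref_spec, radius=radius, output_shape=(360, radius))
    polar = warp_polar(spec, radius=radius, output_shape=(360, radius))
    shift, _, _ = phase_cross_correlation(
        polar_ref, polar, upsample_factor=20, normalization=None
    )
    ang = float(shift[0])
    # spectra have 180-degree symmetry; fold into (-90, 90]
    if ang > 90:
        ang -= 180
    elif ang < -90:
        ang += 180
    return ang


def _log_spectrum(frame: np.ndarray) -> np.ndarray:
    win = np.outer(np.hanning(frame.shape[0]), np.hanning(frame.shape[1]))
    return np.log1p(np.abs(np.fft.fftshift(np.fft.fft2(frame * win))))


def _apply_rigid(frame: np.ndarray, dx: float, dy: float, rot_deg: float) -> np.ndarray:
    out = frame
    if abs(rot_deg) > 1e-6:
        out = ndimage.rotate(out, rot_deg, reshape=False, order=1, mode="nearest")
    if abs(dx) > 1e-9 or abs(dy) > 1e-9:
        out = ndimage.shift(out, (dy, dx), order=1, mode="nearest")
    return out


def _vessel_mask_rough(img: np.ndarray, depth_threshold: float = 0.05) -> np.ndarray:
    """Pixels plausibly inside vessels.

    Works on single (noisy) frames as well as median images: without
    denoising, the grey-closing background estimate rides the noise
    envelope and the depth threshold would flag most of the frame.
    """
    smooth = ndimage.gaussian_filter(img, 2.0)
    size = min(101, 2 * (min(img.shape) // 4) + 1)
    bg = ndimage.grey_closing(smooth, size=(size, size))
    return ndimage.binary_dilation(bg - smooth > depth_threshold, iterations=6)


def register_stack(
    stack: FrameStack,
    reference: Optional[int] = None,
    estimate_rotation: bool = False,
    refine: bool = True,
    upsample_factor: int = 20,
    residual_threshold: Optional[float] = None,
) -> Tuple[FrameStack, RegistrationResult]:
    """Align every frame to the reference with a rigid transform.

    Registration runs in two stages. First, each frame is aligned to
    the reference by masked phase cross-correlation restricted to the
    extravascular background (optionally preceded by a rotation
    estimate from polar-resampled spectral magnitudes): the moving
    blood column is the highest-contrast content in the scene and an
    unmasked correlation would drag the alignment along the vessel axis
    — an aperture problem, since a straight vessel constrains no motion
    along itself. The refinement stage then iterates a sub-pixel
    least-squares (optical-flow style) alignment of every frame to the
    temporal median of the stack — a template of the static scene in
    which the erythrocyte texture is suppressed — again weighted to
    background pixels. The common template offset is removed so the
    reference frame stays bit-exact.

    Parameters
    ----------
    stack : FrameStack
    reference : int, optional
        Reference frame index; defaults to :func:`select_reference`.
    estimate_rotation : bool
        Also estimate in-plane rotation. Off by default: fixation-target
        acquisitions are translation-dominant.
    refine : bool
        Run the median-template refinement passes.
    upsample_factor : int
        Sub-pixel factor of the phase correlations (1/20 px default).
    residual_threshold : float, optional
        Frames whose post-alignment RMS residual to the reference
        exceeds this are flagged as failed and passed through
        untransformed.

    Returns
    -------
    (FrameStack, RegistrationResult)
        The stabilized stack (reference frame bit-exact) and the
        per-frame transforms/residuals.
    """
    if reference is None:
        reference = select_reference(stack)
    if not 0 <= reference < stack.n_frames:
        raise IndexError(f"reference index {reference} out of range")

    T = stack.n_frames
    ref = stack.frames[reference]
    ref_spec = _log_spectrum(ref) if estimate_rotation else None
    radius = min(ref.shape) // 2

    rot = np.zeros(T)
    shifts = np.zeros((T, 2))  # (dy, dx)
    failed: List[int] = []
    warped = np.empty_like(stack.frames)

    # pass 1: masked integer alignment to the reference frame — the
    # vessel interior is excluded from the correlation from the start,
    # because the moving blood column is the brightest-contrast content
    # and would drag the alignment along the vessel axis
    vmask0 = _vessel_mask_rough(ref)
    background = ~vmask0
    use_mask = 0.2 < background.mean() < 1.0
    for i, frame in enumerate(stack.frames):
        if i == reference:
            warped[i] = frame
            continue
        try:
            moving = frame
            if estimate_rotation:
                ang = _estimate_rotation(ref_spec, frame, radius)
                if abs(ang) > 1e-3:
                    moving = ndimage.rotate(frame, ang, reshape=False, order=1, mode="nearest")
                    rot[i] = ang
            if use_mask:
                shift = phase_cross_correlation(
                    ref, moving, reference_mask=background, moving_mask=background
                )[0]
            else:
                shift, _, _ = phase_cross_correlation(
                    ref, moving, upsample_factor=upsample_factor, normalization=None
                )
            shifts[i] = shift
            warped[i] = _apply_rigid(frame, shift[1], shift[0], rot[i])
        except Exception as exc:
            log.warning("registration failed on frame %d: %s", i, exc)
            warped[i] = frame
            failed.append(i)

    if refine and T >= 5:
        ok = [i for i in range(T) if i not in failed]
        # refinement: iterated sub-pixel least-squares alignment to the
        # temporal median (a template of the static scene with the
        # moving erythrocyte texture suppressed), restricted to
        # background pixels
        for _ in range(3):
            median_img = np.median(warped[ok], axis=0)
            vmask = _vessel_mask_rough(median_img)
            w = (~ndimage.binary_dilation(vmask, iterations=2)).astype(float)
            if w.mean() < 0.1:
                w = np.ones_like(w)
            gy, gx = np.gradient(median_img)
            a11 = float(np.sum(w * gy * gy))
            a12 = float(np.sum(w * gy * gx))
            a22 = float(np.sum(w * gx * gx))
            det = a11 * a22 - a12 * a12
            if det <= 1e-12:
                break
            for i in ok:
                diff = warped[i] - median_img
                b1 = float(np.sum(w * gy * diff))
                b2 = float(np.sum(w * gx * diff))
                dy = (a22 * b1 - a12 * b2) / det
                dx = (a11 * b2 - a12 * b1) / det
                d = np.clip([dy, dx], -1.5, 1.5)
                shifts[i] = shifts[i] + d
                warped[i] = _apply_rigid(stack.frames[i], shifts[i][1], shifts[i][0], rot[i])
        # the template offset is arbitrary: re-anchor on the reference
        shifts -= shifts[reference]
        warped[reference] = ref

    transforms: List[Tuple[float, float, float]] = []
    residuals = np.zeros(T)
    out = np.empty_like(stack.frames)
    for i in range(T):
        if i == reference:
            out[i] = ref
            transforms.append((0.0, 0.0, 0.0))
            continue
        if i in failed:
            out[i] = stack.frames[i]
            transforms.append((0.0, 0.0, 0.0))
            residuals[i] = float(np.sqrt(np.mean((stack.frames[i] - ref) ** 2)))
            continue
        frame_out = _apply_rigid(stack.frames[i], shifts[i][1], shifts[i][0], rot[i])
        resid = float(np.sqrt(np.mean((frame_out - ref) ** 2)))
        if residual_threshold is not None and resid > residual_threshold:
            log.warning("frame %d residual %.4g above threshold; passed through", i, resid)
            out[i] = stack.frames[i]
            transforms.append((0.0, 0.0, 0.0))
            residuals[i] = float(np.sqrt(np.mean((stack.frames[i] - ref) ** 2)))
            failed.append(i)
            continue
        out[i] = np.clip(frame_out, 0.0, 1.0)
        transforms.append((float(shifts[i][1]), float(shifts[i][0]), float(rot[i])))
        residuals[i] = resid

    result = RegistrationResult(reference, transforms, residuals, sorted(failed))
    stabilized = FrameStack(out, stack.calibration, source_id=stack.source_id)
    return stabilized, result
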