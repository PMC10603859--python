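"""Two-channel U-Net segmentation of carotid axial slices, supervised by the
adaptive triple Dice loss (ATDL).

The network outputs per-pixel probabilities for the regions enclosed by the
media-adventitia boundary (MAB) and the lumen-intima boundary (LIB). The
loss is a convex combination of three soft Dice losses - MAB, LIB, and the
carotid vessel wall CVW = MAB - LIB - whose weights (a, b, c) always sum to
one. Training starts in a uniform phase (a = b = c = 1/3, which helps the
network localize the vessel); once the smoothed MAB and LIB losses drop
below the CVW loss (or after a warmup), the weights switch to being
proportional to the smoothed component losses with a small floor, which
automatically makes a, b < c and focuses the remaining capacity on the thin
wall region.

Inference uses a flip ensemble (original, horizontal flip, vertical flip;
per-pixel majority vote of the thresholded predictions) and, for internal
carotid slices, a region-of-interest box linearly interpolated between two
user-supplied end boxes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import shapely
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.transform import resize

from .geometry import (Contour, ContourStack, DegenerateContourError,
                       Volume3DUS, clip_inside, contour_from_mask,
                       reslice_stack)
from .nn import Adam, UNet, UNetConfig
from .phantom import CCA_COVERAGE, ICA_COVERAGE, PhantomCase

log = logging.getLogger(__name__)

INPUT_SHAPE = (192, 256)  # (rows, cols) of every network input
DICE_EPS = 1e-6


# ---------------------------------------------------------------------------
# preprocessing and samples
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray,
               shape: Tuple[int, int] = INPUT_SHAPE) -> np.ndarray:
    """Bilinear resample to the network input size (default 192x256) and
    min-max normalize to [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D slice image")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        raise ValueError("constant image cannot be min-max normalized")
    if image.shape != tuple(shape):
        image = resize(image, shape, order=1, mode="edge",
                       anti_aliasing=False)
        lo, hi = float(image.min()), float(image.max())
    return ((image - lo) / (hi - lo)).astype(np.float32)


@dataclass
class SlideSample:
    """One training slice: normalized image plus binary MAB/LIB labels."""
    image: np.ndarray
    y_mab: np.ndarray
    y_lib: np.ndarray
    z: float = 0.0
    vessel: str = "CCA"

    def __post_init__(self):
        if not np.all(self.y_lib <= self.y_mab):
            raise ValueError("LIB label must be a subset of the MAB label")

    @property
    def y_cvw(self) -> np.ndarray:
        return self.y_mab - self.y_lib


def _pixel_geometry(volume: Volume3DUS,
                    shape: Tuple[int, int] = INPUT_SHAPE
                    ) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """((px_x, px_y) mm per network pixel, (x0, y0) mm origin)."""
    nz, ny, nx = volume.voxels.shape
    vx, vy, _ = volume.spacing
    px = nx * vx / shape[1]
    py = ny * vy / shape[0]
    return (px, py), (volume.origin[0], volume.origin[1])


def rasterize_label(contour: Contour, volume: Volume3DUS,
                    shape: Tuple[int, int] = INPUT_SHAPE) -> np.ndarray:
    """Binary network-frame mask of a contour in the volume's slice frame."""
    (px, py), (x0, y0) = _pixel_geometry(volume, shape)
    xs = x0 + (np.arange(shape[1]) + 0.5) * px
    ys = y0 + (np.arange(shape[0]) + 0.5) * py
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(contour.polygon, gx.ravel(), gy.ravel())
    return inside.reshape(shape).astype(np.float32)


def slide_samples_from_case(case: PhantomCase, step: float = 2.0,
                            grid_spacing: float = 0.1,
                            shape: Tuple[int, int] = INPUT_SHAPE
                            ) -> List[SlideSample]:
    """Image/label pairs for every truth slice at longitudinal ``step``."""
    if case.volume is None:
        raise ValueError("case has no rendered volume")
    stack = case.truth if abs(step - case.truth.isd) < 1e-9 else \
        reslice_stack(case.truth, step, grid_spacing=grid_spacing) \
        if step < case.truth.isd else \
        case.geometry.truth_stack(step, z_limits=case.volume.z_range)
    out = []
    for z, (mab, lib) in stack.contours.items():
        k = case.volume.nearest_slice(z)
        img = preprocess(case.volume.voxels[k], shape)
        out.append(SlideSample(
            image=img, y_mab=rasterize_label(mab, case.volume, shape),
            y_lib=rasterize_label(lib, case.volume, shape),
            z=z, vessel=stack.vessel_of(z)))
    return out


def augment_training_set(samples: Sequence[SlideSample],
                         flip_h: bool = True, flip_v: bool = False,
                         n_random: int = 0,
                         max_rotation_deg: float = 15.0,
                         max_translation_frac: float = 0.10,
                         seed: int = 0) -> List[SlideSample]:
    """Geometric augmentation: flips (doubling/quadrupling the count as
    configured) plus ``n_random`` random rotation+translation copies per
    sample, all with labels transformed identically (nearest-neighbour for
    labels, so the LIB-inside-MAB invariant is preserved pixel-wise)."""
    rng = np.random.default_rng(seed)
    out = list(samples)
    if flip_h:
        out = out + [replace(s, image=s.image[:, ::-1].copy(),
                             y_mab=s.y_mab[:, ::-1].copy(),
                             y_lib=s.y_lib[:, ::-1].copy()) for s in out]
    if flip_v:
        out = out + [replace(s, image=s.image[::-1].copy(),
                             y_mab=s.y_mab[::-1].copy(),
                             y_lib=s.y_lib[::-1].copy()) for s in out]
    extra = []
    for s in samples:
        for _ in range(n_random):
            ang = rng.uniform(-max_rotation_deg, max_rotation_deg)
            ty = rng.uniform(-max_translation_frac, max_translation_frac) \
                * s.image.shape[0]
            tx = rng.uniform(-max_translation_frac, max_translation_frac) \
                * s.image.shape[1]
            img = _rot_shift(s.image, ang, (ty, tx), order=1)
            ym = _rot_shift(s.y_mab, ang, (ty, tx), order=0)
            yl = _rot_shift(s.y_lib, ang, (ty, tx), order=0)
            yl = np.minimum(yl, ym)
            if ym.sum() > 16:  # drop samples rotated out of frame
                extra.append(replace(s, image=img, y_mab=ym, y_lib=yl))
    return out + extra


def _rot_shift(a: np.ndarray, angle_deg: float, shift: Tuple[float, float],
               order: int) -> np.ndarray:
    r = ndimage.rotate(a, angle_deg, reshape=False, order=order,
                       mode="constant", cval=float(a.min()))
    return ndimage.shift(r, shift, order=order, mode="constant",
                         cval=float(a.min())).astype(np.float32)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def soft_dice_loss(y: np.ndarray, yhat: np.ndarray,
                   eps: float = DICE_EPS) -> float:
    """1 - 2*sum(y*yhat) / (sum(y) + sum(yhat) + eps)."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError("shape mismatch")
    return float(1.0 - 2.0 * np.sum(y * yhat)
                 / (np.sum(y) + np.sum(yhat) + eps))


def _dice_loss_and_grad(y: np.ndarray, yhat: np.ndarray,
                        eps: float = DICE_EPS):
    """Per-sample soft Dice loss (batch mean) and gradient w.r.t. yhat."""
    axes = tuple(range(1, y.ndim))
    inter = np.sum(y * yhat, axis=axes, keepdims=True)
    s = np.sum(y, axis=axes, keepdims=True) \
        + np.sum(yhat, axis=axes, keepdims=True) + eps
    loss = float(np.mean(1.0 - 2.0 * inter.ravel() / s.ravel()))
    grad = (-2.0 * y / s + 2.0 * inter / s ** 2) / y.shape[0]
    return loss, grad.astype(np.float32)


@dataclass
class ATDLState:
    """Adaptive triple-Dice-loss weights and smoothed component losses."""
    a: float = 1.0 / 3
    b: float = 1.0 / 3
    c: float = 1.0 / 3
    phase: int = 1
    smoothed: Optional[Tuple[float, float, float]] = None
    decay: float = 0.9
    floor: float = 0.05
    warmup_steps: int = 200
    min_steps: int = 20   # burn-in before the smoothed losses are trusted
    step: int = 0

    @property
    def weights(self) -> Tuple[float, float, float]:
        return (self.a, self.b, self.c)


def atdl_step(state: ATDLState,
              losses: Tuple[float, float, float]) -> Tuple[float, ATDLState]:
    """Total ATDL for one step and the updated adaptive state.

    The total uses the state's current weights; the component losses are then
    exponentially smoothed, the phase switches to 2 once the smoothed MAB and
    LIB losses both fall below the CVW loss (or after the warmup), and in
    phase 2 the weights become proportional to the smoothed losses with a
    per-weight floor, renormalized to sum to one.
    """
    l_mab, l_lib, l_cvw = (float(v) for v in losses)
    if min(l_mab, l_lib, l_cvw) < 0:
        raise ValueError("component losses must be nonnegative")
    total = state.a * l_mab + state.b * l_lib + state.c * l_cvw
    if state.smoothed is None:
        sm = (l_mab, l_lib, l_cvw)
    else:
        d = state.decay
        sm = tuple(d * s + (1 - d) * l for s, l in
                   zip(state.smoothed, (l_mab, l_lib, l_cvw)))
    new = replace(state, smoothed=sm, step=state.step + 1)
    if new.phase == 1 and ((new.step >= new.min_steps
                            and sm[0] < sm[2] and sm[1] < sm[2])
                           or new.step >= new.warmup_steps):
        new.phase = 2
    if new.phase == 2:
        tot = sum(sm)
        if tot > 0:
            f = new.floor
            a, b, c = (f + (1 - 3 * f) * s / tot for s in sm)
            new.a, new.b, new.c = a, b, c
    else:
        new.a = new.b = new.c = 1.0 / 3
    return total, new


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 8
    batch_size: int = 4
    lr: float = 2e-3
    seed: int = 0
    stop_loss: Optional[float] = None  # early stop on epoch-mean ATDL
    input_shape: Tuple[int, int] = INPUT_SHAPE  # working resolution
    warmup_epochs: int = 2
    reslice_step: float = 0.5   # mm, training-set reslicing
    flip_h: bool = True
    flip_v: bool = False
    n_random_augment: int = 0
    unet: UNetConfig = field(default_factory=UNetConfig)

    def validate(self):
        if min(self.epochs, self.batch_size) < 1 or self.lr <= 0 \
                or self.reslice_step <= 0:
            raise ValueError("training configuration values must be positive")


@dataclass
class TrainResult:
    model: UNet
    atdl: ATDLState
    history: List[Dict[str, float]]


def train(samples: Sequence[SlideSample],
          config: Optional[TrainConfig] = None,
          model: Optional[UNet] = None) -> TrainResult:
    """Train a two-channel U-Net with ATDL supervision on slide samples."""
    config = config or TrainConfig()
    config.validate()
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = UNet(replace(config.unet, seed=config.seed))
    opt = Adam(model.params(), lr=config.lr)
    steps_per_epoch = max(len(samples) // config.batch_size, 1)
    state = ATDLState(warmup_steps=config.warmup_epochs * steps_per_epoch)
    history: List[Dict[str, float]] = []
    idx = np.arange(len(samples))
    for epoch in range(config.epochs):
        rng.shuffle(idx)
        ep_losses = []
        for b0 in range(0, len(idx) - config.batch_size + 1,
                        config.batch_size):
            batch = [samples[i] for i in idx[b0:b0 + config.batch_size]]
            x = np.stack([s.image for s in batch])[:, None]
            ym = np.stack([s.y_mab for s in batch])
            yl = np.stack([s.y_lib for s in batch])
            yc = ym - yl
            out = model.forward(x, train=True)
            pm, pl = out[:, 0], out[:, 1]
            # wall probability: difference of the channel probabilities,
            # clamped to [0, 1] so its Dice loss stays well-defined
            pc = np.clip(pm - pl, 0.0, 1.0)
            active = ((pm - pl) > 0.0) & ((pm - pl) < 1.0)
            l_mab, g_mab = _dice_loss_and_grad(ym, pm)
            l_lib, g_lib = _dice_loss_and_grad(yl, pl)
            l_cvw, g_cvw = _dice_loss_and_grad(yc, pc)
            g_cvw = g_cvw * active
            total, state = atdl_step(state, (l_mab, l_lib, l_cvw))
            a, b, c = state.weights
            dout = np.empty_like(out)
            dout[:, 0] = a * g_mab + c * g_cvw
            dout[:, 1] = b * g_lib - c * g_cvw
            opt.zero_grad()
            model.backward(dout)
            opt.step()
            ep_losses.append(total)
        history.append({"epoch": epoch, "loss": float(np.mean(ep_losses)),
                        "a": state.a, "b": state.b, "c": state.c,
                        "phase": state.phase})
        log.info("epoch %d: ATDL %.4f (a=%.2f b=%.2f c=%.2f phase %d)",
                 epoch, history[-1]["loss"], state.a, state.b, state.c,
                 state.phase)
        if config.stop_loss is not None \
                and history[-1]["loss"] < config.stop_loss:
            break
    return TrainResult(model=model, atdl=state, history=history)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_with_flip_ensemble(model, image: np.ndarray,
                               threshold: float = 0.5
                               ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel majority vote over {original, horizontal flip, vertical
    flip} predictions; returns boolean (MAB, LIB) masks."""
    x = np.stack([image, image[:, ::-1], image[::-1, :]])[:, None]
    probs = model.forward(np.ascontiguousarray(x), train=False)
    votes = (probs >= threshold)
    votes[1] = votes[1][:, :, ::-1]
    votes[2] = votes[2][:, ::-1, :]
    tally = votes.sum(axis=0)
    return tally[0] >= 2, tally[1] >= 2


def ica_roi_boxes(first_box: Tuple[float, float, float, float],
                  last_box: Tuple[float, float, float, float],
                  zs: Sequence[float],
                  bounds: Optional[Tuple[float, float, float, float]] = None
                  ) -> List[Tuple[float, float, float, float]]:
    """Per-slice axis-aligned boxes, each corner linearly interpolated in z
    between the first (nearest-bifurcation) and last ICA boxes."""
    zs = list(zs)
    if len(zs) < 2:
        raise ValueError("need >= 2 ICA slice positions")
    b0 = np.asarray(first_box, dtype=float)
    b1 = np.asarray(last_box, dtype=float)
    for b in (b0, b1):
        if b[2] <= b[0] or b[3] <= b[1]:
            raise ValueError("box must be (xmin, ymin, xmax, ymax)")
        if bounds is not None and (b[0] < bounds[0] or b[1] < bounds[1]
                                   or b[2] > bounds[2] or b[3] > bounds[3]):
            raise ValueError("box outside the image bounds")
    z0, z1 = zs[0], zs[-1]
    out = []
    for z in zs:
        t = 0.0 if z1 == z0 else (z - z0) / (z1 - z0)
        out.append(tuple((1 - t) * b0 + t * b1))
    return out


def _apply_box(mask: np.ndarray, box, volume: Volume3DUS) -> np.ndarray:
    (px, py), (x0, y0) = _pixel_geometry(volume, mask.shape)
    i0 = int(math.floor((box[0] - x0) / px))
    i1 = int(math.ceil((box[2] - x0) / px))
    j0 = int(math.floor((box[1] - y0) / py))
    j1 = int(math.ceil((box[3] - y0) / py))
    out = np.zeros_like(mask)
    j0, i0 = max(j0, 0), max(i0, 0)
    out[j0:j1, i0:i1] = mask[j0:j1, i0:i1]
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lbl, n = skmeasure.label(mask, return_num=True, connectivity=1)
    if n == 0:
        return mask
    sizes = np.bincount(lbl.ravel())
    sizes[0] = 0
    return lbl == int(np.argmax(sizes))


@dataclass
class SegmentationResult:
    stack: ContourStack
    missing: List[float]  # slice z positions with no usable prediction


def segment_volume(model, volume: Volume3DUS, bifurcation_z: float,
                   ica_end_boxes: Optional[Tuple[tuple, tuple]] = None,
                   isd: float = 2.0, min_pixels: int = 24,
                   input_shape: Tuple[int, int] = INPUT_SHAPE
                   ) -> SegmentationResult:
    """Segment a volume slice-by-slice into a contour stack.

    The bifurcation position and the two ICA end boxes are user inputs (the
    manual interactions of the workflow). Per slice: preprocess, flip-
    ensemble predict, restrict ICA predictions to the interpolated box, keep
    the largest connected component per channel, extract the boundary
    contour, and clip the LIB inside the MAB. Slices with an empty or
    degenerate prediction are flagged missing rather than fabricated.
    """
    z_lo, z_hi = volume.z_range
    zs_cca = bifurcation_z - np.arange(0, CCA_COVERAGE + 1e-9, isd)[::-1]
    zs_ica = bifurcation_z + np.arange(isd, ICA_COVERAGE + 1e-9, isd)
    zs_cca = zs_cca[(zs_cca >= z_lo) & (zs_cca <= z_hi)]
    zs_ica = zs_ica[(zs_ica >= z_lo) & (zs_ica <= z_hi)]
    boxes = None
    if ica_end_boxes is not None and len(zs_ica) >= 2:
        boxes = dict(zip(map(float, zs_ica),
                         ica_roi_boxes(ica_end_boxes[0], ica_end_boxes[1],
                                       zs_ica)))
    (px, py), (x0, y0) = _pixel_geometry(volume, input_shape)
    contours = {}
    missing: List[float] = []
    for z in np.concatenate([zs_cca, zs_ica]):
        img = preprocess(volume.voxels[volume.nearest_slice(z)],
                         input_shape)
        m_mab, m_lib = predict_with_flip_ensemble(model, img)
        if boxes is not None and z > bifurcation_z:
            box = boxes[float(z)]
            m_mab = _apply_box(m_mab, box, volume)
            m_lib = _apply_box(m_lib, box, volume)
        vessel = "CCA" if z <= bifurcation_z else "ICA"
        try:
            if m_mab.sum() < min_pixels:
                raise DegenerateContourError("empty MAB prediction")
            m_mab = _largest_component(m_mab)
            mab = contour_from_mask(m_mab, (px, py),
                                    (x0, y0), float(z), "MAB", vessel)
            m_lib = np.logical_and(m_lib, m_mab)
            if m_lib.sum() < min_pixels:
                raise DegenerateContourError("empty LIB prediction")
            lib = contour_from_mask(_largest_component(m_lib), (px, py),
                                    (x0, y0), float(z), "LIB", vessel)
            if not mab.contains(lib, tol=1e-6):
                lib = clip_inside(mab, lib)
        except (DegenerateContourError, ValueError) as exc:
            log.warning("slice z=%.2f flagged missing: %s", z, exc)
            missing.append(float(z))
            continue
        contours[float(z)] = (mab, lib)
    stack = ContourStack(contours=contours, bifurcation_z=bifurcation_z,
                         isd=isd)
    return SegmentationResult(stack=stack, missing=missing)


class OracleModel:
    """Reference 'model' that returns rasterized truth labels as
    probabilities for every slice image of the cases it was built from.
    Used to validate the segmentation plumbing independently of training."""

    def __init__(self, cases: Sequence[PhantomCase], isd: float = 2.0,
                 shape: Tuple[int, int] = INPUT_SHAPE):
        self._table: Dict[bytes, np.ndarray] = {}
        for case in cases:
            stack = case.geometry.truth_stack(isd,
                                              z_limits=case.volume.z_range)
            for z, (mab, lib) in stack.contours.items():
                img = preprocess(
                    case.volume.voxels[case.volume.nearest_slice(z)], shape)
                out = np.stack([rasterize_label(mab, case.volume, shape),
                                rasterize_label(lib, case.volume, shape)])
                self._table[img.tobytes()] = out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = []
        for img in x[:, 0]:
            for flip in (lambda a: a, lambda a: a[:, ::-1],
                         lambda a: a[::-1, :]):
                key = np.ascontiguousarray(flip(img)).tobytes()
                if key in self._table:
                    outs.append(np.stack([flip(ch)
                                          for ch in self._table[key]]))
                    break
            else:
                outs.append(np.zeros((2,) + img.shape, dtype=np.float32))
        return np.stack(outs)


def ica_end_boxes_from_truth(case: PhantomCase, isd: float = 2.0,
                             pad: float = 1.5) -> Tuple[tuple, tuple]:
    """Ground-truth ICA end boxes (the phantom's stand-in for the manual
    box placement): bounding boxes of the first and last ICA MAB contours,
    padded by ``pad`` mm."""
    z_limits = case.volume.z_range if case.volume is not None else None
    stack = case.geometry.truth_stack(isd, z_limits=z_limits)
    ica = sorted(stack.subset("ICA"))
    if len(ica) < 2:
        raise ValueError("need >= 2 ICA slices")

    def box(z):
        pts = stack.contours[z][0].points
        return (pts[:, 0].min() - pad, pts[:, 1].min() - pad,
                pts[:, 0].max() + pad, pts[:, 1].max() + pad)

    return box(ica[0]), box(ica[-1])
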