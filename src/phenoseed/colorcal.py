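"""Colour calibration: chart patches -> RGB->L*a*b* transfer functions.

The camera's raw output is neither linear nor in a perceptual colour
space, so two models are fitted to colour-checker data:

* an affine RGB->RGB matrix baseline (classic linear calibration, with
  the standard sRGB->L*a*b* conversion applied afterwards), and
* a multi-layer perceptron regressor (MLPR) mapping scaled RGB directly
  to L*a*b*, which folds the nonlinear camera response and the nonlinear
  colour-space transform into a single learned function.

Each 200x200 chart patch is summarised by the channel-wise medians of 50
contiguous 800-pixel regions, which suppresses sensor noise while still
yielding 50 data points per swatch.  Colour differences are reported with
both the Euclidean CIE76 distance and the perceptually weighted CIEDE2000.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color as skcolor
from sklearn.neural_network import MLPRegressor

# 50 regions of 800 px tiling a 200x200 patch: 10 block-rows of 20 px by
# 5 block-cols of 40 px
_PATCH = 200
_BLOCK_R, _BLOCK_C = 20, 40


@dataclass
class CalibrationDataset:
    """Paired (measured scaled RGB, reference L*a*b*) samples for one camera."""

    rgb: np.ndarray  # (n, 3) in [0, 1]
    ref_lab: np.ndarray  # (n, 3)
    camera_id: str = "A"

    def __len__(self) -> int:
        return self.rgb.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            np.hstack([self.rgb, self.ref_lab]),
            columns=["r", "g", "b", "L", "a", "b_ref"],
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, camera_id: str = "A") -> "CalibrationDataset":
        df = pd.read_csv(path)
        return cls(df[["r", "g", "b"]].to_numpy(),
                   df[["L", "a", "b_ref"]].to_numpy(), camera_id)


def extract_patch_medians(patch: np.ndarray) -> np.ndarray:
    """Channel-wise medians of the 50 contiguous 800-px regions of a patch.

    Returns a (50, 3) array in patch-major raster order of the 10x5 block
    grid.  The median makes each region summary robust to isolated noisy
    pixels.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (_PATCH, _PATCH, 3):
        raise ValueError(f"patch must be {_PATCH}x{_PATCH}x3, got {patch.shape}")
    blocks = patch.reshape(
        _PATCH // _BLOCK_R, _BLOCK_R, _PATCH // _BLOCK_C, _BLOCK_C, 3
    )
    med = np.median(blocks, axis=(1, 3))  # (10, 5, 3)
    return med.reshape(50, 3)


def build_dataset(
    patches: list[np.ndarray], refs: np.ndarray, camera_id: str = "A"
) -> CalibrationDataset:
    """Assemble the calibration dataset: 50 median samples per patch, each
    paired with that swatch's reference L*a*b* value.  117 chart swatches
    therefore yield 5850 samples."""
    refs = np.asarray(refs, dtype=float)
    if len(patches) == 0:
        raise ValueError("no patches supplied")
    if len(patches) != refs.shape[0]:
        raise ValueError(f"{len(patches)} patches but {refs.shape[0]} references")
    rgb = np.vstack([extract_patch_medians(p) for p in patches])
    lab = np.repeat(refs, 50, axis=0)
    return CalibrationDataset(rgb, lab, camera_id)


def split_dataset(
    ds: CalibrationDataset, rng_seed: int = 0
) -> tuple[CalibrationDataset, CalibrationDataset, CalibrationDataset]:
    """Disjoint, exhaustive (train, validation, test) split.

    The train pool is floor(0.7 n) samples; floor(0.1 pool) of those are
    held out for validation during training and the remainder of the
    dataset is the test split.
    """
    n = len(ds)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    n_pool = (7 * n) // 10  # floor(0.7 n) in exact integer arithmetic
    n_val = n_pool // 10  # floor(0.1 pool)
    val_idx = perm[:n_val]
    train_idx = perm[n_val:n_pool]
    test_idx = perm[n_pool:]

    def take(idx):
        return CalibrationDataset(ds.rgb[idx], ds.ref_lab[idx], ds.camera_id)

    return take(train_idx), take(val_idx), take(test_idx)


# ---------------------------------------------------------------------------
# colour difference
# ---------------------------------------------------------------------------


def delta_e76(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray | float:
    """CIE76 colour difference: Euclidean distance in L*a*b*."""
    return skcolor.deltaE_cie76(np.asarray(lab1, float), np.asarray(lab2, float))


def delta_e2000(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray | float:
    """CIEDE2000 colour difference with kL = kC = kH = 1."""
    return skcolor.deltaE_ciede2000(np.asarray(lab1, float), np.asarray(lab2, float))


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def fit_linear_rgb(train: CalibrationDataset) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine RGB->RGB calibration.

    Maps measured scaled RGB to the reference colour expressed in scaled
    sRGB.  Returns (matrix 3x3, offset 3); evaluation converts the result
    to L*a*b* before computing colour differences.
    """
    if len(train) < 4:
        raise ValueError("need at least 4 samples for an affine fit")
    X = np.hstack([train.rgb, np.ones((len(train), 1))])
    target = skcolor.lab2rgb(train.ref_lab.reshape(1, -1, 3)).reshape(-1, 3)
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design matrix")
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    return coef[:3].T, coef[3]


def apply_linear_rgb(matrix: np.ndarray, offset: np.ndarray,
                     rgb: np.ndarray) -> np.ndarray:
    """Apply an affine RGB->RGB calibration; output clipped to [0, 1]."""
    out = np.asarray(rgb, float) @ np.asarray(matrix).T + np.asarray(offset)
    return np.clip(out, 0.0, 1.0)


def fit_mlpr(
    train: CalibrationDataset,
    validation: CalibrationDataset,
    rng_seed: int = 0,
    hidden: tuple[int, ...] = (100,),
    max_iter: int = 2000,
    chunk: int = 100,
    patience: int = 4,
) -> tuple[MLPRegressor, dict]:
    """Train the scaled-RGB -> L*a*b* perceptron with Adam.

    Squared error on L*a*b* outputs is the training loss (minimising it is
    equivalent to minimising CIE76 distance squared).  Training proceeds in
    chunks of Adam epochs; after each chunk the mean CIE76 error on the
    held-out validation split is evaluated and training stops once it has
    not improved for ``patience`` chunks.  Returns the model and a training
    report (validation curve, convergence flag).
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    model = MLPRegressor(
        hidden_layer_sizes=hidden,
        solver="adam",
        max_iter=chunk,
        random_state=rng_seed,
        warm_start=True,
        tol=0.0,
    )
    best = np.inf
    best_weights = None
    curve = []
    stale = 0
    converged = False
    n_chunks = max(1, max_iter // chunk)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-chunk max_iter warnings expected
        for _ in range(n_chunks):
            model.fit(train.rgb, train.ref_lab)
            val_de = float(np.mean(delta_e76(validation.ref_lab,
                                             model.predict(validation.rgb))))
            curve.append(val_de)
            if val_de < best - 1e-3:
                best = val_de
                best_weights = ([w.copy() for w in model.coefs_],
                                [b.copy() for b in model.intercepts_])
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    converged = True
                    break
    if best_weights is not None:
        model.coefs_, model.intercepts_ = best_weights
    report = {"validation_de76": curve, "best_validation_de76": best,
              "converged": converged}
    if not converged and len(curve) == n_chunks:
        report["warning"] = "validation error still improving at max_iter"
    return model, report


@dataclass
class ColorModel:
    """A camera's trained colour transfer functions.

    Holds the nonlinear MLPR (RGB -> L*a*b*) alongside the affine RGB->RGB
    baseline, plus the evaluation report produced at training time.
    """

    mlpr: MLPRegressor
    linear_matrix: np.ndarray
    linear_offset: np.ndarray
    camera_id: str = "A"
    training_report: dict = field(default_factory=dict)

    def predict_lab(self, rgb: np.ndarray) -> np.ndarray:
        flat = np.asarray(rgb, float).reshape(-1, 3)
        lab = self.mlpr.predict(flat)
        lab[:, 0] = np.clip(lab[:, 0], 0.0, 100.0)
        return lab.reshape(np.asarray(rgb).shape)

    # -- serialisation: JSON header + .npz weights ---------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        weights = {}
        for i, w in enumerate(self.mlpr.coefs_):
            weights[f"coef_{i}"] = w
        for i, b in enumerate(self.mlpr.intercepts_):
            weights[f"intercept_{i}"] = b
        weights["linear_matrix"] = self.linear_matrix
        weights["linear_offset"] = self.linear_offset
        np.savez(path.with_suffix(".npz"), **weights)
        header = {
            "camera_id": self.camera_id,
            "hidden_layer_sizes": list(self.mlpr.hidden_layer_sizes),
            "n_layers": len(self.mlpr.coefs_),
            "activation": self.mlpr.activation,
            "training_report": self.training_report,
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ColorModel":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        n = header["n_layers"]
        mlpr = MLPRegressor(hidden_layer_sizes=tuple(header["hidden_layer_sizes"]),
                            activation=header["activation"])
        mlpr.coefs_ = [data[f"coef_{i}"] for i in range(n)]
        mlpr.intercepts_ = [data[f"intercept_{i}"] for i in range(n)]
        mlpr.n_layers_ = n + 1
        mlpr.n_outputs_ = mlpr.intercepts_[-1].shape[0]
        mlpr.out_activation_ = "identity"
        mlpr.n_features_in_ = mlpr.coefs_[0].shape[0]
        return cls(mlpr, data["linear_matrix"], data["linear_offset"],
                   header["camera_id"], header["training_report"])


def train_color_model(
    patches: list[np.ndarray],
    refs: np.ndarray,
    camera_id: str = "A",
    rng_seed: int = 0,
) -> ColorModel:
    """End-to-end: patches + references -> fitted ColorModel with report."""
    ds = build_dataset(patches, refs, camera_id)
    train, val, test = split_dataset(ds, rng_seed)
    mlpr, report = fit_mlpr(train, val, rng_seed)
    matrix, offset = fit_linear_rgb(train)
    model = ColorModel(mlpr, matrix, offset, camera_id, report)
    model.training_report.update(evaluate_calibration(model, test))
    return model


def apply_model(model: ColorModel, rgb_image: np.ndarray) -> np.ndarray:
    """Calibrate a scaled-RGB image to L*a*b* via the camera's MLPR."""
    img = np.asarray(rgb_image, dtype=float)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("image must be scaled RGB in [0, 1]")
    return model.predict_lab(img)


def evaluate_calibration(model: ColorModel, test: CalibrationDataset) -> dict:
    """Mean/sd of CIE76 and CIEDE2000 test error for the three variants:
    uncalibrated (plain sRGB->L*a*b* of the raw camera RGB), the affine
    baseline, and the MLPR."""
    if len(test) == 0:
        raise ValueError("empty test set")
    ref = test.ref_lab
    preds = {
        "uncalibrated": skcolor.rgb2lab(test.rgb.reshape(1, -1, 3)).reshape(-1, 3),
        "linear": skcolor.rgb2lab(
            apply_linear_rgb(model.linear_matrix, model.linear_offset, test.rgb)
            .reshape(1, -1, 3)
        ).reshape(-1, 3),
        "mlpr": model.predict_lab(test.rgb),
    }
    out = {}
    for name, lab in preds.items():
        d76 = np.asarray(delta_e76(ref, lab), dtype=float)
        d00 = np.asarray(delta_e2000(ref, lab), dtype=float)
        out[name] = {
            "mean_de76": float(d76.mean()), "sd_de76": float(d76.std()),
            "mean_de2000": float(d00.mean()), "sd_de2000": float(d00.std()),
        }
    return out
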