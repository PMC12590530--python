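"""MechanoOptical classification: augmentation, features, SVM kernels, grouped CV.

Specimens are scarce, so each one is partitioned into non-overlapping segments
(image tiles, AFM sub-grids) that inherit the specimen's control/bleomycin
label.  Cross-validation is grouped at the specimen level (k = 20 by default):
segments of one specimen never span a fold's train/test boundary, which is the
guard against specimen-level leakage.  Four SVM kernels are supported —
linear, RBF, sigmoid and a "ReLU" kernel realized as the order-1 arc-cosine
kernel (the positive-definite kernel whose feature map is an infinite ReLU
network layer).  Fusing the optical and AFM feature blocks per segment gives
the combined "MechanoOptical" classifier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import hog, local_binary_pattern
from sklearn.svm import SVC

from .forcecurves import ElasticityMap
from .synth import Cohort, Specimen, render_specimen_image

__all__ = [
    "SegmentSample",
    "KernelSpec",
    "CVResult",
    "tile_image",
    "split_map",
    "augment_by_segmentation",
    "extract_image_features",
    "extract_afm_features",
    "kernel_eval",
    "gram_matrix",
    "grouped_cv_train_eval",
    "fuse_modalities",
    "external_validate",
    "build_segment_dataset",
    "DEFAULT_GRIDS",
]


@dataclass
class SegmentSample:
    features: np.ndarray
    specimen_id: str
    modality: str  # optical | afm | fused
    label: str     # control | bleomycin
    segment_index: int = 0


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel with its hyperparameter search ranges."""

    kind: str  # linear | relu | rbf | sigmoid
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = ("scale",)
    coef0_grid: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "relu", "rbf", "sigmoid"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("C values must be positive")


# design-decision defaults: C log grid; gamma log-spaced; coef0 {-1, 0, 1}
DEFAULT_GRIDS = {
    "linear": KernelSpec("linear"),
    "relu": KernelSpec("relu"),
    "rbf": KernelSpec("rbf", gamma_grid=("scale", 1e-3, 1e-2, 1e-1, 1.0, 10.0)),
    "sigmoid": KernelSpec(
        "sigmoid",
        gamma_grid=("scale", 1e-3, 1e-2, 1e-1, 1.0, 10.0),
        coef0_grid=(-1.0, 0.0, 1.0),
    ),
}


@dataclass
class CVResult:
    fold_accuracies: list[float]
    fold_params: list[dict]
    k: int
    seed: int
    kernel: str
    is_test_accuracy: bool = True  # structural guarantee: never training accuracy
    warning: str | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def accuracy_range(self) -> tuple[float, float]:
        return (float(min(self.fold_accuracies)), float(max(self.fold_accuracies)))

    @property
    def accuracy_range_percent(self) -> str:
        lo, hi = self.accuracy_range
        return f"{100 * lo:g}-{100 * hi:g}%"


# ---------------------------------------------------------------------------
# Segmentation-based augmentation
# ---------------------------------------------------------------------------

def tile_image(image: np.ndarray, tile: int) -> list[np.ndarray]:
    """Non-overlapping tiles of side ``tile``; a too-large tile returns the
    whole image as a single segment."""
    h, w = image.shape[:2]
    if tile > min(h, w):
        return [image]
    return [
        image[i * tile:(i + 1) * tile, j * tile:(j + 1) * tile]
        for i in range(h // tile)
        for j in range(w // tile)
    ]


def split_map(e_grid: np.ndarray, sub: int) -> list[np.ndarray]:
    """Non-overlapping ``sub x sub`` sub-grids of a modulus map."""
    g = e_grid.shape[0]
    if sub > g:
        return [e_grid]
    return [
        e_grid[i * sub:(i + 1) * sub, j * sub:(j + 1) * sub]
        for i in range(g // sub)
        for j in range(g // sub)
    ]


def augment_by_segmentation(
    specimen_data: dict[str, np.ndarray],
    labels: dict[str, str],
    tile: int,
    kind: str = "image",
) -> list[tuple[str, str, int, np.ndarray]]:
    """Segment each specimen's raw array into disjoint pieces.

    Returns (specimen_id, label, segment_index, segment) tuples; tiling is
    deterministic given the tile size.
    """
    splitter = tile_image if kind == "image" else split_map
    out = []
    for sid, arr in specimen_data.items():
        for idx, seg in enumerate(splitter(arr, tile)):
            out.append((sid, labels[sid], idx, seg))
    return out


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_image_features(
    tile: np.ndarray,
    pixels_per_cell: int = 16,
    orientations: int = 8,
    lbp_points: int = 8,
    lbp_radius: int = 1,
) -> np.ndarray:
    """Fixed-length HOG + uniform-LBP descriptor of one tile.

    The tile is converted to grayscale, min-max normalized (a constant tile
    maps to zeros rather than failing) and center-cropped to a multiple of the
    HOG cell size so the descriptor length is fixed per configuration.
    """
    img = np.asarray(tile, dtype=float)
    if img.ndim == 3:
        img = rgb2gray(img)
    ptp = np.ptp(img)
    img = (img - img.min()) / ptp if ptp > 0 else np.zeros_like(img)

    h, w = img.shape
    ch = (h // pixels_per_cell) * pixels_per_cell
    cw = (w // pixels_per_cell) * pixels_per_cell
    if ch == 0 or cw == 0:
        raise ValueError("tile smaller than one HOG cell")
    top, left = (h - ch) // 2, (w - cw) // 2
    img = img[top:top + ch, left:left + cw]

    hog_vec = hog(
        img,
        orientations=orientations,
        pixels_per_cell=(pixels_per_cell, pixels_per_cell),
        cells_per_block=(1, 1),
        feature_vector=True,
    )
    lbp = local_binary_pattern(
        np.round(img * 255).astype(np.uint8), lbp_points, lbp_radius, method="uniform"
    )
    lbp_hist, _ = np.histogram(lbp, bins=lbp_points + 2, range=(0, lbp_points + 2))
    lbp_hist = lbp_hist / lbp_hist.sum()
    return np.concatenate([hog_vec, lbp_hist])


def extract_afm_features(
    moduli: np.ndarray,
    n_bins: int = 16,
    log_range: tuple[float, float] = (-1.0, 3.0),
) -> np.ndarray:
    """Fixed-length descriptor of a modulus segment (kPa).

    Log-histogram over a global range (16 bins, 0.1-1000 kPa), deciles,
    median, CV% and IQR.  Order-invariant by construction.
    """
    v = np.asarray(moduli, dtype=float).ravel()
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 16:
        raise ValueError("need at least 16 moduli per segment")
    hist, _ = np.histogram(np.log10(v), bins=n_bins, range=log_range)
    hist = hist / v.size
    deciles = np.percentile(v, np.arange(10, 100, 10))
    med = np.median(v)
    cv = 100.0 * v.std(ddof=1) / v.mean() if v.mean() > 0 else 0.0
    q1, q3 = np.percentile(v, [25, 75])
    return np.concatenate([hist, deciles, [med, cv, q3 - q1]])


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def _arccos1_gram(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Order-1 arc-cosine ("ReLU") kernel:
    k(x, y) = (1/pi) |x||y| (sin t + (pi - t) cos t), t the angle between x, y.
    """
    nx = np.linalg.norm(x, axis=1)
    ny = np.linalg.norm(y, axis=1)
    denom = np.outer(nx, ny)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.clip(np.where(denom > 0, (x @ y.T) / denom, 0.0), -1.0, 1.0)
    t = np.arccos(cos_t)
    k = denom / math.pi * (np.sin(t) + (math.pi - t) * cos_t)
    return np.where(denom > 0, k, 0.0)


def gram_matrix(spec: KernelSpec, x: np.ndarray, y: np.ndarray | None = None,
                gamma: float = 1.0, coef0: float = 0.0) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = x if y is None else np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("feature dimensions differ")
    if spec.kind == "linear":
        return x @ y.T
    if spec.kind == "rbf":
        sq = (np.sum(x**2, axis=1)[:, None] + np.sum(y**2, axis=1)[None, :]
              - 2.0 * x @ y.T)
        return np.exp(-gamma * np.clip(sq, 0.0, None))
    if spec.kind == "sigmoid":
        return np.tanh(gamma * (x @ y.T) + coef0)
    return _arccos1_gram(x, y)


def kernel_eval(spec: KernelSpec, x: np.ndarray, y: np.ndarray,
                gamma: float = 1.0, coef0: float = 0.0) -> float:
    """Scalar kernel value between two feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("feature dimensions differ")
    return float(gram_matrix(spec, x[None], y[None], gamma=gamma, coef0=coef0)[0, 0])


# ---------------------------------------------------------------------------
# Grouped cross-validation
# ---------------------------------------------------------------------------

def _make_svc(spec: KernelSpec, c: float, gamma, coef0: float) -> SVC:
    if spec.kind == "relu":
        return SVC(C=c, kernel=lambda a, b: _arccos1_gram(a, b))
    return SVC(C=c, kernel=spec.kind, gamma=gamma, coef0=coef0)


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return tuple((arr - mu) / sd for arr in (train, *others))


def _param_grid(spec: KernelSpec):
    for c in spec.c_grid:
        gammas = spec.gamma_grid if spec.kind in ("rbf", "sigmoid") else ("scale",)
        coef0s = spec.coef0_grid if spec.kind == "sigmoid" else (0.0,)
        for g in gammas:
            for c0 in coef0s:
                yield {"C": c, "gamma": g, "coef0": c0}


def _inner_select(x, y, groups, spec: KernelSpec, rng: np.random.Generator,
                  n_inner: int = 3) -> dict:
    """Pick hyperparameters by grouped inner CV on the training fold."""
    uniq = np.array(sorted(set(groups)))
    params_list = list(_param_grid(spec))
    if len(params_list) == 1 or len(uniq) < n_inner:
        return params_list[0]
    perm = rng.permutation(uniq)
    splits = np.array_split(perm, n_inner)
    best, best_acc = params_list[0], -1.0
    for params in params_list:
        accs = []
        for val_groups in splits:
            val = np.isin(groups, val_groups)
            if val.all() or not val.any() or len(set(y[~val])) < 2:
                continue
            xtr, xval = _standardize(x[~val], x[val])
            clf = _make_svc(spec, params["C"], params["gamma"], params["coef0"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(xtr, y[~val])
            accs.append(float(np.mean(clf.predict(xval) == y[val])))
        acc = float(np.mean(accs)) if accs else -1.0
        if acc > best_acc:
            best, best_acc = params, acc
    return best


def grouped_cv_train_eval(
    samples: list[SegmentSample],
    kernel: KernelSpec,
    k: int = 20,
    seed: int = 0,
    grid_search: bool = True,
    pca_components: int | None = None,
) -> CVResult:
    """Specimen-grouped k-fold cross-validation with inner grid search.

    Specimens (not segments) are shuffled and split into k folds; per fold,
    features are standardized on the training part only, hyperparameters are
    chosen by a grouped inner split of the training specimens, and the fold's
    *test* accuracy is recorded.  If fewer specimen groups than k exist, k is
    lowered with a warning.  ``pca_components`` enables an optional
    dimensionality-reduction stage (PCA fitted on the training fold only);
    it is off by default.
    """
    x = np.vstack([s.features for s in samples])
    y = np.array([s.label for s in samples])
    groups = np.array([s.specimen_id for s in samples])
    uniq = np.array(sorted(set(groups)))
    warning = None
    if len(uniq) < k:
        warning = f"only {len(uniq)} specimen groups: k lowered from {k}"
        k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 specimen groups")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(uniq), k)

    accs, params_used = [], []
    for fold_groups in folds:
        test = np.isin(groups, fold_groups)
        train_groups_mask = ~test
        assert not (set(groups[test]) & set(groups[train_groups_mask])), \
            "specimen leaked across the train/test boundary"
        xtr, xte = _standardize(x[train_groups_mask], x[test])
        if pca_components is not None:
            from sklearn.decomposition import PCA

            pca = PCA(n_components=min(pca_components, *xtr.shape),
                      random_state=0).fit(xtr)
            xtr, xte = pca.transform(xtr), pca.transform(xte)
        if grid_search:
            params = _inner_select(xtr, y[train_groups_mask],
                                   groups[train_groups_mask], kernel, rng)
        else:
            params = next(iter(_param_grid(kernel)))
        clf = _make_svc(kernel, params["C"], params["gamma"], params["coef0"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(xtr, y[train_groups_mask])
        accs.append(float(np.mean(clf.predict(xte) == y[test])))
        params_used.append(params)
    return CVResult(
        fold_accuracies=accs,
        fold_params=params_used,
        k=k,
        seed=seed,
        kernel=kernel.kind,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# Fusion and external validation
# ---------------------------------------------------------------------------

def fuse_modalities(
    optical: list[SegmentSample],
    afm: list[SegmentSample],
    balance_blocks: bool = True,
) -> tuple[list[SegmentSample], dict]:
    """Concatenate block-standardized optical and AFM features per segment.

    Segments are paired within specimen by segment index; specimens present in
    only one modality, and unpaired trailing segments, are dropped with their
    counts reported in the log dictionary.  With ``balance_blocks`` each
    standardized block is scaled by 1/sqrt(its dimension) so a wide descriptor
    (e.g. HOG) cannot drown a compact one in total variance.
    """
    def block(samples):
        f = np.vstack([s.features for s in samples])
        mu, sd = f.mean(axis=0), f.std(axis=0)
        sd[sd == 0] = 1.0
        scale = math.sqrt(f.shape[1]) if balance_blocks else 1.0
        return {(s.specimen_id, s.segment_index): ((s.features - mu) / sd / scale, s)
                for s in samples}

    ob = block(optical)
    ab = block(afm)
    opt_specs = {s.specimen_id for s in optical}
    afm_specs = {s.specimen_id for s in afm}
    shared = opt_specs & afm_specs
    fused = []
    n_unpaired = 0
    for key in sorted(ob):
        sid, idx = key
        if sid not in shared:
            continue
        if key not in ab:
            n_unpaired += 1
            continue
        fo, so = ob[key]
        fa, _ = ab[key]
        fused.append(SegmentSample(
            features=np.concatenate([fo, fa]),
            specimen_id=sid,
            modality="fused",
            label=so.label,
            segment_index=idx,
        ))
    log = {
        "specimens_excluded": sorted((opt_specs | afm_specs) - shared),
        "unpaired_segments_dropped": n_unpaired
        + sum(1 for key in ab if key[0] in shared and key not in ob),
        "n_fused": len(fused),
    }
    return fused, log


@dataclass
class SpecimenCall:
    specimen_id: str
    call: str  # control | bleomycin | indeterminate
    vote_fraction: float
    n_segments: int


def external_validate(
    train_samples: list[SegmentSample],
    holdout_samples: list[SegmentSample],
    kernel: KernelSpec,
    seed: int = 0,
) -> list[SpecimenCall]:
    """Train on one cohort, call each held-out specimen by segment majority vote.

    Exact ties are flagged ``indeterminate`` rather than broken silently.
    """
    train_ids = {s.specimen_id for s in train_samples}
    holdout_ids = {s.specimen_id for s in holdout_samples}
    if train_ids & holdout_ids:
        raise ValueError("holdout specimens overlap the training cohort")
    xtr = np.vstack([s.features for s in train_samples])
    ytr = np.array([s.label for s in train_samples])
    xho = np.vstack([s.features for s in holdout_samples])
    rng = np.random.default_rng(seed)
    params = _inner_select(xtr, ytr, np.array([s.specimen_id for s in train_samples]),
                           kernel, rng)
    xtr_s, xho_s = _standardize(xtr, xho)
    clf = _make_svc(kernel, params["C"], params["gamma"], params["coef0"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(xtr_s, ytr)
    pred = clf.predict(xho_s)

    calls = []
    by_spec: dict[str, list[str]] = {}
    for s, p in zip(holdout_samples, pred):
        by_spec.setdefault(s.specimen_id, []).append(p)
    for sid in sorted(by_spec):
        votes = by_spec[sid]
        n_bleo = votes.count("bleomycin")
        frac = n_bleo / len(votes)
        if frac > 0.5:
            call = "bleomycin"
        elif frac < 0.5:
            call = "control"
        else:
            call = "indeterminate"
        calls.append(SpecimenCall(sid, call, frac, len(votes)))
    return calls


# ---------------------------------------------------------------------------
# Cohort -> segment dataset (the default in-silico experiment)
# ---------------------------------------------------------------------------

def build_segment_dataset(
    cohort: Cohort,
    image_size: int = 256,
    image_tile: int = 64,
    map_subgrid: int = 4,
    hog_pixels_per_cell: int = 32,
) -> tuple[list[SegmentSample], list[SegmentSample]]:
    """Render per-specimen histology and AFM maps and segment both modalities.

    Returns (optical samples, afm samples); with the defaults each specimen
    contributes 16 image tiles of 64 px and, from one 16x16 map, 16 AFM
    sub-grids of 4x4 (16 curves each), so the two modalities pair one-to-one
    for fusion.  The local sub-grids keep segment-level AFM noisy enough that
    the optical view carries complementary information.
    """
    optical, afm = [], []
    for spec in cohort.specimens:
        imgset = render_specimen_image(spec, size=image_size)
        for idx, tile in enumerate(tile_image(imgset.polarized, image_tile)):
            optical.append(SegmentSample(
                features=extract_image_features(tile, pixels_per_cell=hog_pixels_per_cell),
                specimen_id=spec.specimen_id,
                modality="optical",
                label=spec.label,
                segment_index=idx,
            ))
        idx = 0
        for emap in spec.true_maps:
            values = np.where(emap.qc_mask, emap.e_kpa, np.nan)
            for seg in split_map(values, map_subgrid):
                afm.append(SegmentSample(
                    features=extract_afm_features(seg),
                    specimen_id=spec.specimen_id,
                    modality="afm",
                    label=spec.label,
                    segment_index=idx,
                ))
                idx += 1
    return optical, afm
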