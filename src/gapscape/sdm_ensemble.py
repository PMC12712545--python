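"""Species-distribution modelling with a TSS-weighted ensemble.

The workflow mirrors standard presence/background ensemble practice:

1. occurrence cleaning — exact-duplicate removal and 1-km spatial
   thinning (random, seed-reproducible removal within the radius);
2. predictor filtering — greedy elimination of highly correlated layers
   (|Pearson r| > 0.8), keeping the member of each offending pair with
   the higher univariate importance (point-biserial correlation with
   presence/background labels);
3. member models — a surface-range envelope (SRE) and a ridge-penalized
   logistic regression with quadratic terms are built in; prediction
   rasters from external algorithms can join the ensemble as-is;
4. repeated 75/25 train/test splits (default 10 runs) with 500 uniform
   background points per run; member skill = mean TSS across runs;
5. the weighted-mean ensemble  P = sum_i w_i P_i  over members whose
   TSS exceeds 0.8, with w_i proportional to TSS_i (sum w_i = 1);
6. binarization at the ensemble's own max-TSS threshold, Jenks 3-class
   suitability levels above the threshold, and richness stacking of the
   per-species high-suitability masks.

Evaluation metrics: AUC via the rank statistic with midranks for ties,
TSS maximized by an exact sweep over the unique predicted values
(prediction >= threshold means "suitable"; ties in TSS break toward the
lower threshold, i.e. the larger suitable area), and Cohen's kappa at
the max-TSS threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .core_io import Grid, jenks_breaks

RICHNESS_CLASSES = ["none", "low", "moderate", "relatively_high", "high"]
#: richness-count bins: 0 / 1-2 / 3-4 / 5-6 / >=7 species
RICHNESS_BIN_EDGES = [1, 3, 5, 7]


@dataclass
class OccurrenceSet:
    species: str
    points: np.ndarray  # (n, 2) map coordinates
    provenance: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.provenance is None:
            self.provenance = ["unknown"] * len(self.points)


@dataclass
class ModelEvaluation:
    auc: float
    tss: float
    kappa: float
    threshold_at_max_tss: float


@dataclass
class EnsembleMember:
    model_id: str
    prediction: Grid
    tss: float


@dataclass
class EnsembleModel:
    members: list[EnsembleMember]
    weights: np.ndarray
    inclusion_threshold: float
    all_member_tss: dict[str, float]


@dataclass
class SuitabilitySurface:
    species: str
    p_ens: Grid
    binary: Grid
    classes: Grid        # 0 unsuitable, 1 low, 2 medium, 3 high
    high_mask: Grid
    threshold: float
    evaluation: ModelEvaluation
    test_presence_scores: np.ndarray = field(default=None, repr=False)
    test_background_scores: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# occurrence handling
# ---------------------------------------------------------------------------

def thin_occurrences(raw: OccurrenceSet, radius_km: float = 1.0,
                     seed: int = 0) -> OccurrenceSet:
    """Spatially thin points so no two are closer than ``radius_km``.

    Exact duplicates are removed first; then points are visited in a
    seeded random order and kept only if no already-kept point lies
    within the radius — reproducing "randomly selected records within
    spatial proximity were removed".
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    pts = raw.points
    if len(pts) == 0:
        warnings.warn(f"{raw.species}: empty occurrence set")
        return OccurrenceSet(raw.species, np.empty((0, 2)))
    pts = np.unique(pts, axis=0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pts))
    kept: list[np.ndarray] = []
    r_m = radius_km * 1000.0
    for i in order:
        p = pts[i]
        if all(np.hypot(*(p - q)) >= r_m for q in kept):
            kept.append(p)
    return OccurrenceSet(raw.species, np.array(kept))


def thin_table(df: pd.DataFrame, radius_km: float = 1.0,
               seed: int = 0) -> pd.DataFrame:
    """Thin an occurrence table (species, x, y) per species."""
    out = []
    for i, (sp, grp) in enumerate(sorted(df.groupby("species"))):
        occ = thin_occurrences(
            OccurrenceSet(sp, grp[["x", "y"]].to_numpy()),
            radius_km=radius_km, seed=seed + i)
        out.append(pd.DataFrame({"species": sp, "x": occ.points[:, 0],
                                 "y": occ.points[:, 1]}))
    return pd.concat(out, ignore_index=True)


def points_to_cells(points: np.ndarray, geom: Grid) -> np.ndarray:
    """Map (x, y) points to (row, col) cell indices."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    out = np.array([geom.point_to_cell(x, y) for x, y in pts], dtype=int)
    return out.reshape(-1, 2)


def _values_at(layers: list[Grid], cells: np.ndarray) -> np.ndarray:
    return np.column_stack([lyr.values[cells[:, 0], cells[:, 1]]
                            for lyr in layers])


# ---------------------------------------------------------------------------
# predictor filtering
# ---------------------------------------------------------------------------

def filter_predictors(layers: list[Grid], occurrences: np.ndarray,
                      r_max: float = 0.8,
                      background_cells: np.ndarray | None = None
                      ) -> tuple[list[Grid], list[int]]:
    """Greedy collinearity filtering of predictor layers.

    While any pair of remaining layers has |Pearson r| > ``r_max`` over
    the non-nodata cells, the member of the worst pair with the lower
    univariate importance is dropped.  Importance is the absolute
    point-biserial correlation between layer values and presence (1) /
    background (0) labels; background defaults to all valid cells.

    Returns the retained layers and their original indices.
    """
    if len(layers) < 2:
        return list(layers), list(range(len(layers)))
    geom = layers[0]
    valid = ~geom.nodata_mask
    data = np.column_stack([lyr.values[valid] for lyr in layers])

    pres_cells = points_to_cells(occurrences, geom) if len(occurrences) else \
        np.empty((0, 2), dtype=int)
    if background_cells is None:
        bg_vals = data
    else:
        bg_vals = _values_at(layers, background_cells)
    pres_vals = _values_at(layers, pres_cells) if len(pres_cells) else \
        np.empty((0, len(layers)))
    labels = np.r_[np.ones(len(pres_vals)), np.zeros(len(bg_vals))]
    stacked = np.vstack([pres_vals, bg_vals])
    importance = np.zeros(len(layers))
    if len(pres_vals) and labels.std() > 0:
        for j in range(len(layers)):
            if stacked[:, j].std() > 0:
                importance[j] = abs(np.corrcoef(stacked[:, j], labels)[0, 1])

    keep = list(range(len(layers)))
    while len(keep) > 1:
        sub = data[:, keep]
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(R, 0.0)
        R = np.nan_to_num(np.abs(R))
        if R.max() <= r_max:
            break
        a, b = np.unravel_index(np.argmax(R), R.shape)
        ia, ib = keep[a], keep[b]
        drop = ia if importance[ia] <= importance[ib] else ib
        keep.remove(drop)
    return [layers[i] for i in keep], keep


def sample_background(geom: Grid, n: int = 500, seed: int = 0,
                      exclude_cells: np.ndarray | None = None) -> np.ndarray:
    """Uniform random non-nodata cells, excluding presence cells.

    Returns (n, 2) array of (row, col) indices, seed-reproducible.
    """
    valid = ~geom.nodata_mask
    if exclude_cells is not None and len(exclude_cells):
        valid = valid.copy()
        ex = np.asarray(exclude_cells, dtype=int).reshape(-1, 2)
        valid[ex[:, 0], ex[:, 1]] = False
    pool = np.flatnonzero(valid.ravel())
    if n > pool.size:
        raise ValueError(f"requested {n} background cells, only {pool.size} available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n, replace=False)
    r, c = np.unravel_index(chosen, geom.shape)
    return np.column_stack([r, c])


# ---------------------------------------------------------------------------
# member models
# ---------------------------------------------------------------------------

def fit_envelope(train_presence_cells: np.ndarray, layers: list[Grid],
                 q: float = 0.025) -> Grid:
    """Surface-range-envelope suitability.

    Cell score = fraction of layers whose value at the cell lies within
    the [q, 1-q] quantile interval of the presence values.
    """
    if len(train_presence_cells) < 5:
        raise ValueError("envelope model needs at least 5 presence points")
    geom = layers[0]
    score = np.zeros(geom.shape)
    pres = _values_at(layers, train_presence_cells)
    for j, lyr in enumerate(layers):
        lo, hi = np.quantile(pres[:, j], [q, 1 - q])
        score += ((lyr.values >= lo) & (lyr.values <= hi)).astype(float)
    return geom.like(score / len(layers))


def fit_logistic(train_presence_cells: np.ndarray,
                 train_background_cells: np.ndarray, layers: list[Grid],
                 l2: float = 0.1, degree: int = 2) -> Grid:
    """Ridge-penalized logistic regression of presence vs background.

    Layer values are standardized on the training data and expanded with
    quadratic terms (``degree=2``) so unimodal niche responses are
    representable, as in the conventional polynomial GLM used in
    ensemble SDM platforms.  With ``l2 = 0`` (no penalty) complete
    separation raises an error instructing a positive penalty.
    """
    geom = layers[0]
    Xp = _values_at(layers, train_presence_cells)
    Xb = _values_at(layers, train_background_cells)
    X = np.vstack([Xp, Xb])
    y = np.r_[np.ones(len(Xp)), np.zeros(len(Xb))]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0

    def design(M: np.ndarray) -> np.ndarray:
        Z = (M - mu) / sd
        if degree >= 2:
            Z = np.hstack([Z, Z ** 2])
        return Z

    if l2 > 0:
        clf = LogisticRegression(penalty="l2", C=1.0 / l2, max_iter=2000)
    else:
        clf = LogisticRegression(penalty=None, max_iter=2000)
    Z = design(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, y)
    if l2 <= 0:
        s = clf.decision_function(Z)
        if s[y == 1].min() > s[y == 0].max():
            raise ValueError("complete separation with l2=0; set l2 > 0")
    full = np.column_stack([lyr.values.ravel() for lyr in layers])
    p = clf.predict_proba(design(full))[:, 1].reshape(geom.shape)
    return geom.like(p)


def load_external_prediction(pred: Grid | str, model_id: str,
                             geom: Grid, tss_claim: float | None = None
                             ) -> EnsembleMember:
    """Admit an externally produced suitability raster as a member.

    Values must lie in [0, 1] (outside the nodata mask) and the grid
    must align with the study geometry.  The claimed TSS is replaced by
    an internal re-evaluation whenever test data are supplied to
    :func:`ensemble`.
    """
    if isinstance(pred, str):
        from .core_io import read_grid
        pred = read_grid(pred)
    if not pred.aligned_with(geom):
        raise ValueError(f"external prediction {model_id!r}: grid misaligned")
    v = pred.valid()
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError(
            f"external prediction {model_id!r}: values outside [0, 1]")
    return EnsembleMember(model_id=model_id, prediction=pred,
                          tss=float("nan") if tss_claim is None else tss_claim)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def evaluate_scores(presence_scores: np.ndarray,
                    background_scores: np.ndarray) -> ModelEvaluation:
    """AUC / max-TSS / kappa from raw presence and background scores."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need non-empty presence and background test sets")
    ranks = rankdata(np.r_[p, b])
    auc = (ranks[:len(p)].sum() - len(p) * (len(p) + 1) / 2) / (len(p) * len(b))
    best_tss, best_thr, best_kappa = -np.inf, None, 0.0
    for thr in np.unique(np.r_[p, b]):
        sens = np.mean(p >= thr)
        spec = np.mean(b < thr)
        tss = sens + spec - 1.0
        if tss > best_tss:  # ties keep the first (lowest) threshold
            best_tss, best_thr = tss, thr
            best_kappa = _kappa(p, b, thr)
    return ModelEvaluation(auc=float(auc), tss=float(best_tss),
                           kappa=float(best_kappa),
                           threshold_at_max_tss=float(best_thr))


def _kappa(p: np.ndarray, b: np.ndarray, thr: float) -> float:
    tp = np.sum(p >= thr)
    fn = len(p) - tp
    fp = np.sum(b >= thr)
    tn = len(b) - fp
    n = len(p) + len(b)
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    return (po - pe) / (1 - pe) if pe < 1 else 0.0


def evaluate(pred: Grid, test_presence_cells: np.ndarray,
             test_background_cells: np.ndarray) -> ModelEvaluation:
    """Evaluate a prediction grid at test presence/background cells."""
    ps = pred.values[test_presence_cells[:, 0], test_presence_cells[:, 1]]
    bs = pred.values[test_background_cells[:, 0], test_background_cells[:, 1]]
    return evaluate_scores(ps, bs)


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

INTERNAL_MODELS = ("SRE", "GLM")


def _fit_internal(model_id: str, pres: np.ndarray, bg: np.ndarray,
                  layers: list[Grid]) -> Grid:
    if model_id == "SRE":
        return fit_envelope(pres, layers)
    if model_id == "GLM":
        return fit_logistic(pres, bg, layers)
    raise KeyError(f"unknown internal model {model_id!r}")


def ensemble(species: str, presence_cells: np.ndarray, layers: list[Grid],
             runs: int = 10, split: float = 0.75, seed: int = 0,
             n_background: int = 500, inclusion_threshold: float = 0.8,
             models: tuple[str, ...] = INTERNAL_MODELS,
             external: list[EnsembleMember] | None = None
             ) -> tuple[EnsembleModel, SuitabilitySurface]:
    """TSS-weighted ensemble over repeated train/test splits.

    Per run the presences are resplit (default 75/25), a fresh uniform
    background sample is drawn, each internal member is refit and scored
    on the held-out points.  A member's skill is its mean TSS over runs;
    members above the inclusion threshold enter the weighted mean with
    weights proportional to TSS.  The ensemble surface is binarized at
    its own max-TSS threshold computed on the pooled held-out points,
    and above-threshold suitabilities are split into low/medium/high by
    Jenks natural breaks.
    """
    geom = layers[0]
    rng = np.random.default_rng(seed)
    n = len(presence_cells)
    if n < 8:
        raise ValueError(f"{species}: too few presences ({n}) to split")
    n_bg_avail = int((~geom.nodata_mask).sum()) - n
    n_bg = min(n_background, n_bg_avail)

    run_tss: dict[str, list[float]] = {m: [] for m in models}
    run_preds: dict[str, list[np.ndarray]] = {m: [] for m in models}
    pooled_test_p: list[np.ndarray] = []
    pooled_test_b: list[np.ndarray] = []
    for _ in range(runs):
        perm = rng.permutation(n)
        n_tr = max(1, int(round(split * n)))
        tr_p, te_p = presence_cells[perm[:n_tr]], presence_cells[perm[n_tr:]]
        bg = sample_background(geom, n=n_bg, seed=int(rng.integers(2**31)),
                               exclude_cells=presence_cells)
        bperm = rng.permutation(len(bg))
        n_btr = max(1, int(round(split * len(bg))))
        tr_b, te_b = bg[bperm[:n_btr]], bg[bperm[n_btr:]]
        pooled_test_p.append(te_p)
        pooled_test_b.append(te_b)
        for m in models:
            pred = _fit_internal(m, tr_p, tr_b, layers)
            run_preds[m].append(pred.values)
            run_tss[m].append(evaluate(pred, te_p, te_b).tss)

    test_p = np.vstack(pooled_test_p)
    test_b = np.vstack(pooled_test_b)
    members: list[EnsembleMember] = []
    for m in models:
        mean_pred = geom.like(np.mean(run_preds[m], axis=0))
        members.append(EnsembleMember(m, mean_pred, float(np.mean(run_tss[m]))))
    for ext in external or []:
        tss = evaluate(ext.prediction, test_p, test_b).tss \
            if np.isnan(ext.tss) else ext.tss
        members.append(EnsembleMember(ext.model_id, ext.prediction, tss))

    all_tss = {mb.model_id: mb.tss for mb in members}
    qualified = [mb for mb in members if mb.tss > inclusion_threshold]
    if not qualified:
        raise RuntimeError(
            f"{species}: no member exceeds TSS {inclusion_threshold}; "
            f"member TSS = {all_tss}")
    w = np.array([mb.tss for mb in qualified])
    w = w / w.sum()
    p_ens = geom.like(sum(wi * mb.prediction.values
                          for wi, mb in zip(w, qualified)))
    model = EnsembleModel(members=qualified, weights=w,
                          inclusion_threshold=inclusion_threshold,
                          all_member_tss=all_tss)
    surface = _build_surface(species, p_ens, test_p, test_b)
    return model, surface


def _build_surface(species: str, p_ens: Grid, test_p: np.ndarray,
                   test_b: np.ndarray) -> SuitabilitySurface:
    ev = evaluate(p_ens, test_p, test_b)
    thr = ev.threshold_at_max_tss
    valid = ~p_ens.nodata_mask
    binary = (p_ens.values >= thr) & valid
    classes = np.zeros(p_ens.shape, dtype=np.int32)
    above = p_ens.values[binary]
    if above.size:
        uniq = np.unique(above)
        kk = min(3, len(uniq))
        if kk == 1:
            classes[binary] = 3
        else:
            edges = jenks_breaks(above, kk).edges
            ci = np.clip(np.searchsorted(edges, p_ens.values, side="right"),
                         1, kk) + (3 - kk)
            classes[binary] = ci[binary]
    high = classes == 3
    ps = p_ens.values[test_p[:, 0], test_p[:, 1]]
    bs = p_ens.values[test_b[:, 0], test_b[:, 1]]
    return SuitabilitySurface(
        species=species, p_ens=p_ens, binary=p_ens.like(binary),
        classes=p_ens.like(classes), high_mask=p_ens.like(high),
        threshold=thr, evaluation=ev,
        test_presence_scores=ps, test_background_scores=bs)


def stack_richness(surfaces: list[SuitabilitySurface]) -> dict:
    """Species richness = count of per-species high-suitability masks.

    Richness levels follow the conventional bins: none (0), low (1-2),
    moderate (3-4), relatively high (5-6), high (>= 7 species).
    """
    if not surfaces:
        raise ValueError("no suitability surfaces to stack")
    geom = surfaces[0].p_ens
    for s in surfaces[1:]:
        geom.require_aligned(s.p_ens, "suitability surfaces")
    richness = np.zeros(geom.shape, dtype=np.int32)
    for s in surfaces:
        richness += s.high_mask.values.astype(np.int32)
    cls = np.searchsorted(RICHNESS_BIN_EDGES, richness, side="right")
    valid = ~geom.nodata_mask
    fractions = {name: float(np.sum((cls == i) & valid)) / int(valid.sum())
                 for i, name in enumerate(RICHNESS_CLASSES)}
    return {"richness": geom.like(richness),
            "classes": geom.like(cls.astype(np.int32)),
            "class_fractions": fractions}


def evaluation_table(results: dict[str, tuple[EnsembleModel, SuitabilitySurface]]
                     ) -> pd.DataFrame:
    """Flat per-species, per-member evaluation table."""
    rows = []
    for sp, (model, surf) in results.items():
        for mb in model.members:
            rows.append({"species": sp, "model": mb.model_id, "tss": mb.tss,
                         "weight": float(model.weights[
                             [m.model_id for m in model.members].index(mb.model_id)])})
        rows.append({"species": sp, "model": "ENSEMBLE",
                     "tss": surf.evaluation.tss, "auc": surf.evaluation.auc,
                     "kappa": surf.evaluation.kappa,
                     "threshold": surf.threshold})
    return pd.DataFrame(rows)
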