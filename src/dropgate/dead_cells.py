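"""Stage 4 (optional): dead-cell scoring, labelling and consensus refinement.

Every QC-passing barcode gets a score built from arcsine-transformed
ribosomal (R) and coding (C) UMI fractions and centred log total UMIs (U)
and log detected features (F):

    score = -11.82 U + 2.08 F + 158.98 R + 18.87 C F - 125.9 R C

Low scores mark putative dead cells (more UMIs, higher coding fraction,
depleted ribosomal content). Initial labels come from the first knee of
the score EDF in its lower tail; the labels are then refined by ten
independent runs of an adaptive-resampling ridge (L2 logistic) classifier
on an SVD embedding, and only barcodes with the same label in at least
8/10 runs are called. Runs fail — and every barcode reverts to live —
when labelling halts or consensus is too incomplete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.model_selection import StratifiedKFold

from .expression_filter import embed, select_hvgs
from .matrix_io import CountMatrix
from .robust import knee_point

logger = logging.getLogger("dropgate")

__all__ = [
    "SCORE_COEFFS",
    "dead_features",
    "dead_score",
    "InitialLabels",
    "initial_dead_labels",
    "DeadCellResult",
    "refine_dead_labels",
    "flag_dead",
]

# score = cU*U + cF*F + cR*R + cCF*C*F + cRC*R*C
SCORE_COEFFS = {"U": -11.82, "F": 2.08, "R": 158.98, "CF": 18.87, "RC": -125.9}

N_RUNS = 10
N_EPOCHS = 10
CONSENSUS_MIN = 8
MAX_UNRESOLVED_FRAC = 0.10
KENDALL_P = 0.05
JITTER_SD = 0.1
PROB_CUTOFF = 0.5
CS_GRID = np.logspace(-4, 4, 100)


def dead_features(qc: pd.DataFrame, arcsine_sqrt: bool = True) -> pd.DataFrame:
    """Arcsine-transformed fractions and centred log counts.

    R and C are asin(sqrt(p)) / (pi/2) by default (the variance-stabilising
    form), mapping [0,1] -> [0,1] with 0.5 a fixed point; set
    ``arcsine_sqrt=False`` for the plain asin(p) / (pi/2) variant. U and F
    are log totals / log detected features centred over the scored set.
    """
    half_pi = np.pi / 2
    ribo = qc["frac_ribo"].to_numpy(dtype=float)
    coding = qc["frac_coding"].to_numpy(dtype=float)
    if arcsine_sqrt:
        ribo, coding = np.sqrt(ribo), np.sqrt(coding)
    r = np.arcsin(ribo) / half_pi
    c = np.arcsin(coding) / half_pi
    u = np.log(qc["total_umis"].to_numpy(dtype=float))
    f = np.log(qc["n_features"].to_numpy(dtype=float))
    return pd.DataFrame(
        {"U": u - u.mean(), "F": f - f.mean(), "R": r, "C": c}, index=qc.index
    )


def dead_score(features: pd.DataFrame) -> np.ndarray:
    """The fixed-coefficient dead-cell score (low = dead-like)."""
    U = features["U"].to_numpy(dtype=float)
    F = features["F"].to_numpy(dtype=float)
    R = features["R"].to_numpy(dtype=float)
    C = features["C"].to_numpy(dtype=float)
    k = SCORE_COEFFS
    return k["U"] * U + k["F"] * F + k["R"] * R + k["CF"] * C * F + k["RC"] * R * C


@dataclass
class InitialLabels:
    dead: np.ndarray  # boolean per scored barcode
    knee_score: float
    knee_quantile_used: float
    success: bool
    halted_reason: str | None = None


def initial_dead_labels(scores: np.ndarray) -> InitialLabels:
    """Data-adaptive initial dead labels from the score EDF.

    Finds the first knee of the empirical distribution function between
    the 0% quantile and an upper quantile starting at 10% (raised in
    steps of 10% while nothing is labelled); scores strictly below the
    knee are putative dead. Labelling halts (success = False) when fewer
    than 3 or more than 10% of barcodes end up dead-labelled, or when no
    knee exists.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 30:
        raise ValueError("initial_dead_labels requires >= 30 barcodes")
    if np.ptp(scores) == 0:
        return InitialLabels(np.zeros(n, bool), np.nan, 0.1, False, "no_knee")

    srt = np.sort(scores)
    u = 0.10
    dead = np.zeros(n, bool)
    knee_score = np.nan
    while u <= 1.0 + 1e-9:
        hi = np.quantile(scores, min(u, 1.0))
        window = srt[srt <= hi]
        if window.size >= 3 and np.ptp(window) > 0:
            ecdf = np.searchsorted(srt, window, side="right") / n
            knee = knee_point(window, ecdf)
            if not knee.degenerate and knee.index >= 1:
                knee_score = float(window[knee.index])
                # bimodal window: when one score gap below the knee dominates
                # the window range, the EDF's first knee is where that gap
                # ends — snap the threshold there
                gaps = np.diff(window[: knee.index + 1])
                j = int(np.argmax(gaps))
                if gaps[j] > 0.5 * np.ptp(window):
                    knee_score = float(window[j + 1])
                dead = scores < knee_score
                if dead.any():
                    break
        u += 0.10
    else:
        return InitialLabels(np.zeros(n, bool), np.nan, min(u, 1.0), False, "no_knee")

    n_dead = int(dead.sum())
    if n_dead < 3:
        return InitialLabels(np.zeros(n, bool), knee_score, u, False, "too_few_dead")
    if n_dead > 0.10 * n:
        return InitialLabels(np.zeros(n, bool), knee_score, u, False, "too_many_dead")
    return InitialLabels(dead, knee_score, u, True)


@dataclass
class DeadCellResult:
    barcode_ids: list[str]
    score: np.ndarray
    initial_label: np.ndarray  # "dead" / "live" / "none"
    run_labels: np.ndarray | None  # n_runs x n boolean (dead = True)
    consensus_label: np.ndarray  # "dead" / "live" / "unresolved"
    success: bool
    knee_quantile_used: float = np.nan
    halted_reason: str | None = None

    @property
    def n_dead(self) -> int:
        return int(np.sum(self.consensus_label == "dead")) if self.success else 0

    @property
    def per_barcode(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dead_score": self.score,
                "dead_initial": self.initial_label,
                "dead_consensus": self.consensus_label,
            },
            index=pd.Index(self.barcode_ids, name="barcode_id"),
        )


def _select_components(embedding: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Components with two-sided Kendall-tau p < 0.05 against the labels
    (at least 2; else the top 5 by |tau|)."""
    taus, ps = [], []
    y = labels.astype(float)
    for j in range(embedding.shape[1]):
        t, p = kendalltau(embedding[:, j], y)
        taus.append(0.0 if np.isnan(t) else t)
        ps.append(1.0 if np.isnan(p) else p)
    taus, ps = np.array(taus), np.array(ps)
    keep = np.flatnonzero(ps < KENDALL_P)
    if keep.size < 2:
        keep = np.argsort(-np.abs(taus))[:5]
    return np.sort(keep)


class RidgeLogistic:
    """L2-penalised logistic regression fitted by damped IRLS.

    The inverse penalty C is chosen by stratified k-fold cross-validation
    of the out-of-fold deviance (log loss) over a log-spaced grid,
    warm-starting along the path — the binomial-deviance CV scheme of
    penalised-regression packages. The intercept is unpenalised.
    """

    def __init__(self, Cs: np.ndarray = CS_GRID, n_folds: int = 5):
        self.Cs = np.asarray(Cs, dtype=float)
        self.n_folds = n_folds
        self.coef_: np.ndarray | None = None
        self.C_: float = np.nan

    @staticmethod
    def _irls_path(
        X: np.ndarray, y: np.ndarray, Cs: np.ndarray, beta0: np.ndarray | None = None
    ) -> np.ndarray:
        n, p = X.shape
        Xb = np.hstack([X, np.ones((n, 1))])
        beta = np.zeros(p + 1) if beta0 is None else beta0.copy()
        yv = y.astype(float)
        out = np.empty((len(Cs), p + 1))

        def penalised_loss(b, lam):
            eta = np.clip(Xb @ b, -30, 30)
            ll = np.sum(np.log1p(np.exp(eta)) - yv * eta)
            return ll + 0.5 * lam * np.dot(b[:p], b[:p])

        for i, C in enumerate(Cs):
            lam = 1.0 / C
            loss = penalised_loss(beta, lam)
            for _ in range(50):
                eta = np.clip(Xb @ beta, -30, 30)
                mu = 1.0 / (1.0 + np.exp(-eta))
                grad = Xb.T @ (mu - yv)
                grad[:p] += lam * beta[:p]
                if np.linalg.norm(grad) < 1e-8 * max(1, n):
                    break
                w = np.maximum(mu * (1 - mu), 1e-6)
                H = (Xb * w[:, None]).T @ Xb
                H[np.arange(p), np.arange(p)] += lam
                step = np.linalg.solve(H, grad)
                # damped Newton: halve until the penalised loss decreases
                t = 1.0
                for _ in range(12):
                    cand = beta - t * step
                    cand_loss = penalised_loss(cand, lam)
                    if cand_loss <= loss + 1e-12:
                        break
                    t *= 0.5
                if cand_loss > loss:
                    break
                beta, loss = cand, cand_loss
            out[i] = beta
        return out

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> "RidgeLogistic":
        y = np.asarray(y, dtype=bool)
        min_class = int(min(y.sum(), (~y).sum()))
        n_folds = min(self.n_folds, min_class)
        if n_folds >= 2:
            fold_seed = int(rng.integers(0, 2**31 - 1))
            cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
            loss = np.zeros(len(self.Cs))
            for tr, te in cv.split(X, y.astype(int)):
                betas = self._irls_path(X[tr], y[tr], self.Cs)
                eta = np.clip(
                    np.hstack([X[te], np.ones((len(te), 1))]) @ betas.T, -30, 30
                )
                prob = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
                yv = y[te].astype(float)[:, None]
                loss += -np.mean(yv * np.log(prob) + (1 - yv) * np.log(1 - prob), axis=0)
            best = int(np.argmin(loss))  # ties -> strongest penalty
            self.C_ = float(self.Cs[best])
            path = self._irls_path(X, y, self.Cs[: best + 1])
            self.coef_ = path[-1]
        else:  # too few members of one class to cross-validate
            self.C_ = 1.0
            self.coef_ = self._irls_path(X, y, np.array([1.0]))[0]
        return self

    def predict_proba_dead(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(X @ self.coef_[:-1] + self.coef_[-1], -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))


def _fit_ridge(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> RidgeLogistic:
    """Ridge-logistic fit with penalty chosen by (up to) 5-fold deviance CV
    on a 100-point log-spaced grid; folds shrink when a class is tiny."""
    return RidgeLogistic().fit(X, y, rng)


def refine_dead_labels(
    counts: CountMatrix,
    initial_dead: np.ndarray,
    seed: int = 0,
    n_hvgs: int = 2000,
    n_components: int = 100,
) -> DeadCellResult:
    """Consensus refinement of noisy dead/live labels.

    Ten independent runs, each up to ten epochs of: Kendall-tau component
    selection against the current labels, resampling training labels from
    the previous epoch's class probabilities, feature jitter (sd = 0.1 x
    per-feature sd), an L2 logistic fit with 5-fold CV over a 100-point
    penalty grid, and relabelling at probability 0.5 (early stop when
    labels are stable). A barcode is called only when >= 8/10 runs agree;
    if more than 10% of barcodes lack consensus the whole run fails and
    every label reverts to live.
    """
    initial_dead = np.asarray(initial_dead, dtype=bool)
    n = initial_dead.size
    if n != counts.n_barcodes:
        raise ValueError("labels/matrix size mismatch")
    if initial_dead.all() or not initial_dead.any():
        raise ValueError("initial labels must contain both classes")

    master = np.random.SeedSequence(seed)
    embed_seed = int(np.random.default_rng(master.spawn(1)[0]).integers(0, 2**31 - 1))
    hvgs = select_hvgs(counts, n_hvgs)
    embedding = embed(counts, hvgs, n_components=min(n_components, n - 1), seed=embed_seed)
    feat_sd = embedding.std(axis=0)
    feat_sd[feat_sd == 0] = 1.0

    run_labels = np.zeros((N_RUNS, n), dtype=bool)
    for run, ss in enumerate(master.spawn(N_RUNS)):
        rng = np.random.default_rng(ss)
        labels = initial_dead.copy()
        prob_dead: np.ndarray | None = None
        for epoch in range(N_EPOCHS):
            keep = _select_components(embedding, labels)
            X = embedding[:, keep]
            if epoch == 0 or prob_dead is None:
                y = labels.copy()
            else:
                y = rng.random(n) < prob_dead
            if y.all() or not y.any():
                break  # degenerate resample; keep current labels
            Xj = X + rng.normal(0.0, JITTER_SD * feat_sd[keep][None, :], X.shape)
            clf = _fit_ridge(Xj, y, rng)
            prob_dead = clf.predict_proba_dead(X)
            new = prob_dead > PROB_CUTOFF
            if np.array_equal(new, labels):
                labels = new
                break
            labels = new
        run_labels[run] = labels

    dead_votes = run_labels.sum(axis=0)
    consensus = np.full(n, "unresolved", dtype=object)
    consensus[dead_votes >= CONSENSUS_MIN] = "dead"
    consensus[(N_RUNS - dead_votes) >= CONSENSUS_MIN] = "live"
    unresolved = float(np.mean(consensus == "unresolved"))
    success = unresolved <= MAX_UNRESOLVED_FRAC
    if not success:
        logger.warning("consensus failure: %.1f%% of barcodes unresolved", 100 * unresolved)
        consensus = np.full(n, "live", dtype=object)

    initial = np.where(initial_dead, "dead", "live").astype(object)
    return DeadCellResult(
        barcode_ids=list(counts.barcode_ids),
        score=np.full(n, np.nan),
        initial_label=initial,
        run_labels=run_labels,
        consensus_label=consensus,
        success=success,
        halted_reason=None if success else "consensus_failure",
    )


def flag_dead(
    counts: CountMatrix,
    qc: pd.DataFrame,
    seed: int = 0,
    n_hvgs: int = 2000,
    n_components: int = 100,
) -> DeadCellResult:
    """Score, initially label and consensus-refine dead-cell flags.

    Scoring and initial labelling run on stage-2 survivors; refinement and
    reporting are restricted to stage-3 survivors. When no stage-3
    survivor is initially dead-labelled, the highest-scoring putative-dead
    barcode is temporarily included in the refinement set (and excluded
    from the final report). A halted initial labelling returns success =
    False with every label live.
    """
    s2_ids = qc.index[qc["pass_stage2"]]
    s3_ids = qc.index[qc["pass_stage3"]] if "pass_stage3" in qc.columns else s2_ids
    feats = dead_features(qc.loc[s2_ids])
    scores = dead_score(feats)
    score_of = pd.Series(scores, index=s2_ids)

    def _failed(reason: str, quantile: float = np.nan) -> DeadCellResult:
        return DeadCellResult(
            barcode_ids=list(s3_ids),
            score=score_of.reindex(s3_ids).to_numpy(),
            initial_label=np.full(len(s3_ids), "none", dtype=object),
            run_labels=None,
            consensus_label=np.full(len(s3_ids), "live", dtype=object),
            success=False,
            knee_quantile_used=quantile,
            halted_reason=reason,
        )

    try:
        init = initial_dead_labels(scores)
    except ValueError:
        return _failed("too_few_barcodes")
    if not init.success:
        return _failed(init.halted_reason or "halted", init.knee_quantile_used)

    dead_of = pd.Series(init.dead, index=s2_ids)
    refine_ids = list(s3_ids)
    temp_barcode = None
    if not dead_of.reindex(s3_ids).fillna(False).any():
        putative = score_of[dead_of]
        if putative.empty:
            return _failed("too_few_dead", init.knee_quantile_used)
        temp_barcode = putative.idxmax()  # least dead-like putative-dead barcode
        refine_ids = refine_ids + [temp_barcode]
        logger.info("temporarily including putative-dead barcode %s in refinement", temp_barcode)

    pos = {b: i for i, b in enumerate(counts.barcode_ids)}
    idx = np.array([pos[b] for b in refine_ids])
    sub = counts.subset_barcodes(idx)
    # subset_barcodes sorts indices; recover the barcode order of the subset
    sub_ids = sub.barcode_ids
    initial_sub = dead_of.reindex(sub_ids).fillna(False).to_numpy(dtype=bool)

    result = refine_dead_labels(sub, initial_sub, seed=seed, n_hvgs=n_hvgs, n_components=n_components)

    out = pd.DataFrame(
        {
            "consensus": pd.Series(result.consensus_label, index=sub_ids),
            "initial": pd.Series(result.initial_label, index=sub_ids),
        }
    ).reindex(s3_ids)
    return DeadCellResult(
        barcode_ids=list(s3_ids),
        score=score_of.reindex(s3_ids).to_numpy(),
        initial_label=out["initial"].fillna("none").to_numpy(dtype=object),
        run_labels=None,
        consensus_label=(
            out["consensus"].fillna("live").to_numpy(dtype=object)
            if result.success
            else np.full(len(s3_ids), "live", dtype=object)
        ),
        success=result.success,
        knee_quantile_used=init.knee_quantile_used,
        halted_reason=result.halted_reason,
    )
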