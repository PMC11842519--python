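"""Chemotherapy-response prediction: feature assembly, shadow-feature
selection, random-forest training and representative-tree distillation.

The modelling surface follows the Model/Results convention: build a
:class:`ChemoResponseModel` from an assembled :class:`FeatureMatrix` (or
straight from a cohort with :meth:`ChemoResponseModel.from_cohort`), call
``fit()`` and receive a :class:`ChemoResponseResults` carrying the selected
features, the fitted ensemble, out-of-bag and held-out AUCs, the distilled
representative tree and a ``summary()`` table.

Selection is a shadow-feature (Boruta-style) wrapper: every iteration
appends a permuted copy of each feature, fits a random forest, and counts a
"hit" whenever a real feature's importance beats the best shadow; a
Bonferroni-corrected binomial test on hit counts promotes features to
Confirmed or demotes them to Rejected.  Distillation selects the ensemble
member most faithful to the full ensemble's predictions on held-out data,
then refits it as a single cost-complexity-pruned tree.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedShuffleSplit, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, export_graphviz, export_text

from ._utils import child_seed, rank_auc, stream
from .io import ClinicalTable
from .immune import (
    FractionMatrix,
    assign_immune_subgroups,
    deconvolve_fractions,
    signature_score,
)
from .io import log_offset_transform, row_zscore

POSITIVE_LABEL = "Responder"
NEGATIVE_LABEL = "Non-responder"


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Assembled per-sample feature table with binary response labels."""

    X: pd.DataFrame                      # samples x features
    y: pd.Series                         # Responder / Non-responder
    kinds: dict[str, str] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)  # feature -> source

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share sample ids in order")
        bad = set(self.y.dropna()) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValueError(f"unexpected labels: {sorted(bad)}")
        constant = [c for c in self.X.columns if self.X[c].nunique() <= 1]
        if constant:
            raise ValueError(f"constant features must be dropped before assembly: {constant}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset_samples(self, ids) -> "FeatureMatrix":
        fm = FeatureMatrix.__new__(FeatureMatrix)
        fm.X = self.X.loc[ids]
        fm.y = self.y.loc[ids]
        fm.kinds = self.kinds
        fm.manifest = self.manifest
        return fm

    @property
    def y_binary(self) -> np.ndarray:
        return (self.y == POSITIVE_LABEL).to_numpy()


def map_response_labels(response_category: pd.Series) -> pd.Series:
    """RECIST-style mapping: CR/PR -> Responder, SD/PD -> Non-responder."""
    mapping = {"CR": POSITIVE_LABEL, "PR": POSITIVE_LABEL,
               "SD": NEGATIVE_LABEL, "PD": NEGATIVE_LABEL}
    unknown = set(response_category.dropna()) - set(mapping)
    if unknown:
        raise ValueError(f"unknown response categories: {sorted(unknown)}")
    return response_category.map(mapping).rename("label")


def assemble_features(
    fractions: FractionMatrix,
    subgroups: pd.Series,
    gene_set_scores: pd.DataFrame,
    cn_exposures: pd.DataFrame,
    flags: pd.DataFrame,
    clinical: ClinicalTable,
) -> FeatureMatrix:
    """Join per-sample features from every module into one labelled table.

    Numeric features are median-imputed then column-standardised; categorical
    features (immune subgroup, clinical categories, MSI status) are one-hot
    encoded with an explicit NA level; binary flags stay 0/1.  Constant
    columns are dropped (logged in the manifest as dropped).
    """
    parts = {
        "immune_fractions": fractions.fractions,
        "gene_set_scores": gene_set_scores,
        "cn_exposures": cn_exposures,
    }
    ids = set(clinical.sample_ids)
    for name, df in list(parts.items()) + [("subgroups", subgroups.to_frame()),
                                           ("flags", flags)]:
        other = set(df.index)
        if other != ids:
            diff = sorted(ids.symmetric_difference(other))
            raise ValueError(f"sample ids of {name} differ from clinical: {diff[:10]}")
    order = list(clinical.sample_ids)
    y = map_response_labels(clinical.data["response_category"]).loc[order]

    cols: dict[str, pd.Series] = {}
    kinds: dict[str, str] = {}
    manifest: dict[str, str] = {}

    def add_numeric(series: pd.Series, name: str, source: str) -> None:
        vals = pd.to_numeric(series.loc[order], errors="coerce")
        vals = vals.fillna(vals.median())
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0 or vals.nunique() <= 1:
            manifest[name] = f"{source} (dropped: constant)"
            return
        cols[name] = (vals - vals.mean()) / sd
        kinds[name] = "numeric"
        manifest[name] = source

    def add_categorical(series: pd.Series, name: str, source: str) -> None:
        vals = series.loc[order].astype(object).where(series.loc[order].notna(), "NA")
        for level in sorted(map(str, set(vals))):
            col = f"{name}_{level}"
            indicator = (vals.astype(str) == level).astype(float)
            if indicator.nunique() <= 1:
                manifest[col] = f"{source} (dropped: constant)"
                continue
            cols[col] = indicator
            kinds[col] = "categorical-encoded"
            manifest[col] = source

    def add_binary(series: pd.Series, name: str, source: str) -> None:
        vals = series.loc[order].astype(bool).astype(float)
        if vals.nunique() <= 1:
            manifest[name] = f"{source} (dropped: constant)"
            return
        cols[name] = vals
        kinds[name] = "binary"
        manifest[name] = source

    for ct in fractions.cell_types:
        add_numeric(fractions.fractions[ct], f"fraction_{ct}", "immune_profiling")
    add_categorical(subgroups, "subgroup", "immune_profiling")
    for s in gene_set_scores.columns:
        add_numeric(gene_set_scores[s], f"score_{s}", "immune_profiling")
    for s in cn_exposures.columns:
        add_numeric(cn_exposures[s], f"cn_{s}", "cn_signatures")
    if "msi_status" in flags.columns:
        add_categorical(flags["msi_status"], "msi", "variant_rules")
    for f in ("pgx_positive", "ebv_positive", "hp_positive"):
        if f in flags.columns:
            add_binary(flags[f], f, "variant_rules")
    clin = clinical.data
    if "age" in clin.columns:
        add_numeric(clin["age"], "age", "clinical")
    for c in ("gender", "histology", "tissue_type", "cT", "cN"):
        if c in clin.columns:
            add_categorical(clin[c], c, "clinical")

    X = pd.DataFrame(cols, index=pd.Index(order, name="sample"))
    return FeatureMatrix(X=X, y=y, kinds=kinds, manifest=manifest)


# ---------------------------------------------------------------------------
# Shadow-feature (Boruta-style) selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureDecision:
    status: pd.Series                    # Confirmed / Tentative / Rejected
    importance_history: pd.DataFrame     # iterations x features (NaN once inactive)
    hits: pd.Series
    trials: pd.Series
    n_iterations: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.status[self.status == "Confirmed"].index)

    @property
    def tentative(self) -> list[str]:
        return list(self.status[self.status == "Tentative"].index)


def boruta_select(fm: FeatureMatrix, max_iter: int = 200, alpha: float = 0.01,
                  seed: int = 0, n_estimators: int = 100) -> FeatureDecision:
    """All-relevant feature selection against permuted shadow features.

    Each iteration appends an independently permuted shadow copy of every
    still-active feature, fits a random forest, and scores a hit for every
    real feature whose impurity importance exceeds the best shadow's.  A
    two-sided binomial test on the hit count (null p = 0.5), Bonferroni
    corrected across the original feature count, promotes to Confirmed or
    demotes to Rejected; rejected features leave the forest.  Deterministic
    given the seed.
    """
    if max_iter < 10:
        raise ValueError("max_iter must be >= 10")
    features = fm.feature_names
    if len(features) < 2:
        raise ValueError("need at least 2 features")
    y = fm.y_binary
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    rng = stream(seed, "boruta")
    m = len(features)
    status = pd.Series("Tentative", index=features, name="status")
    hits = pd.Series(0, index=features, dtype=int)
    trials = pd.Series(0, index=features, dtype=int)
    history = []
    x_full = fm.X.to_numpy(dtype=float)

    it = 0
    for it in range(1, max_iter + 1):
        active = [f for f in features if status[f] != "Rejected"]
        if not (status == "Tentative").any():
            it -= 1
            break
        idx = [features.index(f) for f in active]
        x_act = x_full[:, idx]
        # at least 5 shadow columns (cycling through active features) so the
        # max-shadow bar stays competitive late in the run
        n_shadow = max(len(active), 5)
        shadows = np.column_stack([
            rng.permutation(x_act[:, j % x_act.shape[1]])
            for j in range(n_shadow)])
        x_aug = np.hstack([x_act, shadows])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=child_seed(seed, f"boruta_rf_{it}"),
            n_jobs=1,
        )
        rf.fit(x_aug, y)
        imp = rf.feature_importances_
        real_imp = imp[: len(active)]
        shadow_max = imp[len(active):].max()
        row = pd.Series(np.nan, index=features)
        row[active] = real_imp
        history.append(row)
        for f, v in zip(active, real_imp):
            trials[f] += 1
            if v > shadow_max:
                hits[f] += 1
        # decision step: two one-sided binomial tails, Bonferroni-corrected
        # over features x decision looks (the test recurs every iteration,
        # so the correction universe includes the sequential looks)
        thresh = alpha / (m * it)
        for f in active:
            if status[f] != "Tentative":
                continue
            p_hi = stats.binom.sf(hits[f] - 1, trials[f], 0.5)
            p_lo = stats.binom.cdf(hits[f], trials[f], 0.5)
            if p_hi < thresh:
                status[f] = "Confirmed"
            elif p_lo < thresh:
                status[f] = "Rejected"

    hist = pd.DataFrame(history, index=range(1, len(history) + 1))
    return FeatureDecision(status=status, importance_history=hist,
                           hits=hits, trials=trials, n_iterations=it)


# ---------------------------------------------------------------------------
# Learner comparison
# ---------------------------------------------------------------------------

def compare_models(fm: FeatureMatrix, n_repeats: int = 30,
                   test_fraction: float = 0.30, seed: int = 0) -> pd.DataFrame:
    """Mean/sd test accuracy of RF, linear max-margin and Gaussian NB over
    repeated stratified 70/30 splits; the winner is flagged."""
    y = fm.y_binary
    if min(y.sum(), (~y).sum()) < 2:
        raise ValueError("each class needs at least 2 samples")
    x = fm.X.to_numpy(dtype=float)
    learners = {
        "random_forest": lambda s: RandomForestClassifier(
            n_estimators=200, random_state=s, n_jobs=1),
        "svm_linear": lambda s: SVC(kernel="linear", random_state=s),
        "naive_bayes": lambda s: GaussianNB(),
    }
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_fraction,
        random_state=child_seed(seed, "compare_split"))
    acc = {name: [] for name in learners}
    for rep, (tr, te) in enumerate(splitter.split(x, y)):
        for name, make in learners.items():
            clf = make(child_seed(seed, f"compare_{name}_{rep}"))
            clf.fit(x[tr], y[tr])
            acc[name].append(float((clf.predict(x[te]) == y[te]).mean()))
    out = pd.DataFrame(
        {
            "mean_accuracy": {k: float(np.mean(v)) for k, v in acc.items()},
            "sd_accuracy": {k: float(np.std(v, ddof=1)) for k, v in acc.items()},
        }
    )
    out["winner"] = out["mean_accuracy"] == out["mean_accuracy"].max()
    return out


# ---------------------------------------------------------------------------
# Training, evaluation, distillation
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    estimator: RandomForestClassifier
    features: list[str]
    feature_medians: pd.Series
    oob_auc: float
    oob_scores: pd.Series
    importances: pd.Series

    def scores(self, X: pd.DataFrame) -> np.ndarray:
        """Responder vote fraction for each row of a feature table."""
        pos = list(self.estimator.classes_).index(True)
        return self.estimator.predict_proba(X[self.features].to_numpy())[:, pos]


@dataclass
class EvaluationReport:
    auc: float
    accuracy: float
    roc: pd.DataFrame  # fpr, tpr, threshold
    scores: pd.Series


def train_and_evaluate(fm_train: FeatureMatrix,
                       fm_test: Optional[FeatureMatrix] = None,
                       features: Optional[Sequence[str]] = None,
                       seed: int = 0, n_estimators: int = 500,
                       allow_tentative: bool = False,
                       decision: Optional[FeatureDecision] = None,
                       ) -> tuple[TrainedModel, Optional[EvaluationReport]]:
    """Fit the bagged-tree ensemble on the selected features.

    ``features`` normally comes from the Confirmed set of
    :func:`boruta_select`; if it is empty and ``allow_tentative`` is not set
    an error instructs the caller to fall back to Tentative features
    explicitly.  AUC is the rank statistic with ties credited 0.5, computed
    on out-of-bag votes for training and on the vote fraction for held-out
    data.
    """
    if features is None and decision is not None:
        features = decision.confirmed
        if not features:
            if allow_tentative:
                features = decision.tentative
            else:
                raise ValueError(
                    "no Confirmed features; pass allow_tentative=True to fall "
                    "back to Tentative features")
    if not features:
        raise ValueError("no features to train on")
    features = list(features)
    x = fm_train.X[features].to_numpy(dtype=float)
    y = fm_train.y_binary
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        criterion="gini",
        oob_score=True,
        bootstrap=True,
        random_state=child_seed(seed, "rf_train"),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(x, y)
    pos = list(rf.classes_).index(True)
    oob = rf.oob_decision_function_[:, pos]
    oob = np.nan_to_num(oob, nan=0.5)  # samples never out-of-bag get 0.5
    trained = TrainedModel(
        estimator=rf,
        features=features,
        feature_medians=fm_train.X[features].median(),
        oob_auc=rank_auc(oob, y),
        oob_scores=pd.Series(oob, index=fm_train.sample_ids, name="oob_score"),
        importances=pd.Series(rf.feature_importances_, index=features,
                              name="importance").sort_values(ascending=False),
    )
    report = None
    if fm_test is not None:
        report = evaluate(trained, fm_test)
    return trained, report


def evaluate(model: TrainedModel, fm: FeatureMatrix) -> EvaluationReport:
    scores = model.scores(fm.X)
    y = fm.y_binary
    fpr, tpr, thr = roc_curve(y, scores)
    return EvaluationReport(
        auc=rank_auc(scores, y),
        accuracy=float(((scores >= 0.5) == y).mean()),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        scores=pd.Series(scores, index=fm.sample_ids, name="score"),
    )


@dataclass
class RepresentativeTree:
    tree: DecisionTreeClassifier
    features: list[str]
    features_used: list[str]
    fidelity: float
    nodes: pd.DataFrame

    def to_text(self) -> str:
        return export_text(self.tree, feature_names=self.features)

    def to_dot(self) -> str:
        return export_graphviz(
            self.tree, feature_names=self.features,
            class_names=[NEGATIVE_LABEL, POSITIVE_LABEL], filled=False)


def _tree_features(tree, features: Sequence[str]) -> set[str]:
    used = {int(i) for i in tree.tree_.feature if i >= 0}
    return {features[i] for i in used}


def _tree_nodes_table(tree, features: Sequence[str]) -> pd.DataFrame:
    t = tree.tree_
    rows = []
    for node in range(t.node_count):
        leaf = t.children_left[node] == -1
        counts = t.value[node][0]
        frac = counts / counts.sum() if counts.sum() else counts
        rows.append({
            "node": node,
            "feature": None if leaf else features[t.feature[node]],
            "threshold": np.nan if leaf else float(t.threshold[node]),
            "left": int(t.children_left[node]),
            "right": int(t.children_right[node]),
            "leaf_class": (POSITIVE_LABEL if frac[-1] >= 0.5 else NEGATIVE_LABEL)
            if leaf else None,
            "class_fractions": tuple(np.round(frac, 4)),
        })
    return pd.DataFrame(rows).set_index("node")


def distill_tree(model: TrainedModel, fm_heldout: FeatureMatrix,
                 fm_train: FeatureMatrix,
                 top_features: Optional[Sequence[str]] = None,
                 min_top_k: int = 2) -> RepresentativeTree:
    """Distill the ensemble into one representative decision tree.

    Candidate trees are ensemble members using at least ``min_top_k`` of the
    top-ranked features; the winner maximises fidelity — agreement with the
    full ensemble's predictions on held-out data — with ties broken by fewer
    nodes then lower index.  The winner is then refit as a single tree on
    its own features against the ensemble's predicted labels and pruned by
    cost-complexity, with the pruning level again chosen by held-out
    fidelity.
    """
    rf = model.estimator
    features = model.features
    if top_features is None:
        top_features = list(model.importances.index[:6])
    top = set(top_features)
    x_held = fm_heldout.X[features].to_numpy(dtype=float)
    ens_pred_held = rf.predict(x_held)

    overlaps = [len(_tree_features(t, features) & top) for t in rf.estimators_]
    candidates = [i for i, o in enumerate(overlaps) if o >= min_top_k]
    if not candidates:
        warnings.warn("no ensemble member uses enough top features; "
                      "falling back to best-overlap trees")
        best_overlap = max(overlaps)
        candidates = [i for i, o in enumerate(overlaps) if o == best_overlap]

    def fidelity_of(tree) -> float:
        return float((tree.predict(x_held) == ens_pred_held).mean())

    scored = sorted(
        ((fidelity_of(rf.estimators_[i]), -rf.estimators_[i].tree_.node_count, -i)
         for i in candidates),
        reverse=True)
    winner_idx = -scored[0][2]
    winner = rf.estimators_[winner_idx]
    winner_features = sorted(_tree_features(winner, features) | (top & set(features)))

    # refit as a single pruned tree against the ensemble's own predictions
    x_train_sub = fm_train.X[winner_features].to_numpy(dtype=float)
    y_distill = rf.predict(fm_train.X[features].to_numpy(dtype=float))
    x_held_sub = fm_heldout.X[winner_features].to_numpy(dtype=float)
    base = DecisionTreeClassifier(random_state=0)
    path = base.cost_complexity_pruning_path(x_train_sub, y_distill)
    scored_prunes = []
    for alpha in np.unique(path.ccp_alphas):
        t = DecisionTreeClassifier(random_state=0, ccp_alpha=float(alpha))
        t.fit(x_train_sub, y_distill)
        fid = float((t.predict(x_held_sub) == ens_pred_held).mean())
        k_top = len(_tree_features(t, winner_features) & top)
        scored_prunes.append((t, fid, float(alpha), k_top))
    # prefer pruning levels that keep >= min_top_k top features in the tree;
    # among those maximise fidelity, ties towards stronger pruning
    eligible = [s for s in scored_prunes if s[3] >= min_top_k] or scored_prunes
    best_tree, best_fid, _, _ = max(eligible, key=lambda s: (s[1], s[2]))
    return RepresentativeTree(
        tree=best_tree,
        features=winner_features,
        features_used=sorted(_tree_features(best_tree, winner_features)),
        fidelity=best_fid,
        nodes=_tree_nodes_table(best_tree, winner_features),
    )


def external_validate(model: TrainedModel, fm_external: FeatureMatrix) -> dict:
    """Score an external cohort mapped by feature name.

    Features absent from the external table are imputed with training
    medians (count reported); less than 50% overlap is an error.
    """
    present = [f for f in model.features if f in fm_external.X.columns]
    if len(present) < 0.5 * len(model.features):
        raise ValueError(
            f"only {len(present)}/{len(model.features)} model features present "
            "in the external cohort (need >= 50%)")
    X = pd.DataFrame(index=fm_external.X.index)
    for f in model.features:
        if f in fm_external.X.columns:
            X[f] = fm_external.X[f]
        else:
            X[f] = model.feature_medians[f]
    scores = model.scores(X)
    y = fm_external.y_binary
    bins = np.clip((scores * 5).astype(int), 0, 4)
    calib = pd.DataFrame({
        "bin": [f"[{b / 5:.1f},{(b + 1) / 5:.1f})" for b in range(5)],
        "n": [int((bins == b).sum()) for b in range(5)],
        "mean_score": [float(scores[bins == b].mean()) if (bins == b).any() else np.nan
                       for b in range(5)],
        "responder_rate": [float(y[bins == b].mean()) if (bins == b).any() else np.nan
                           for b in range(5)],
    }).set_index("bin")
    return {
        "auc": rank_auc(scores, y),
        "n_imputed_features": len(model.features) - len(present),
        "feature_coverage": len(present) / len(model.features),
        "calibration": calib,
        "scores": pd.Series(scores, index=fm_external.X.index, name="score"),
    }


# ---------------------------------------------------------------------------
# Model / Results layer
# ---------------------------------------------------------------------------

def engineer_features(expression, segments, variants, clinical, pathogen_counts,
                      reference=None, gene_sets=None, k_subgroups: int = 4,
                      nmf_rank: int = 2, nmf_restarts: int = 10,
                      seed: int = 0) -> tuple[FeatureMatrix, dict]:
    """Run every upstream module and assemble the feature matrix.

    Returns the feature matrix plus a dict of intermediate artifacts
    (fractions, subgroups, signature scores, signature set, flags).
    """
    from .cnsig import encode_cn_contexts, extract_signatures, match_to_catalog
    from .synthetic import default_gene_sets, default_reference
    from .variants import build_flags

    reference = default_reference() if reference is None else reference
    gene_sets = default_gene_sets() if gene_sets is None else gene_sets

    fractions = deconvolve_fractions(expression, reference)
    subgroups = assign_immune_subgroups(fractions, k=k_subgroups, seed=seed)
    z = row_zscore(log_offset_transform(expression))
    scores = pd.DataFrame({gs.name: signature_score(z, gs) for gs in gene_sets})
    contexts = encode_cn_contexts(segments)
    sigs = match_to_catalog(extract_signatures(
        contexts, rank=nmf_rank, n_restarts=nmf_restarts, seed=seed))
    exposures = sigs.exposures.rename(
        columns={k: f"{k}_{v[0]}" for k, v in sigs.assignments.items()})
    flags = build_flags(variants, pathogen_counts, clinical.sample_ids)
    fm = assemble_features(fractions, subgroups, scores, exposures,
                           flags.flags, clinical)
    artifacts = {
        "fractions": fractions,
        "subgroups": subgroups,
        "gene_set_scores": scores,
        "signatures": sigs,
        "contexts": contexts,
        "flags": flags,
    }
    return fm, artifacts


class ChemoResponseModel:
    """Response-prediction model over an assembled feature matrix.

    Parameters mirror the pipeline's protocol: a stratified 70/30 split,
    shadow-feature selection on the training portion, a bagged-tree ensemble
    on the Confirmed features, and representative-tree distillation scored
    on the held-out portion.
    """

    def __init__(self, features: FeatureMatrix, *, test_fraction: float = 0.30,
                 boruta_max_iter: int = 200, boruta_alpha: float = 0.01,
                 boruta_trees: int = 100, n_estimators: int = 500,
                 min_top_k: int = 2, seed: int = 0):
        self.features = features
        self.test_fraction = test_fraction
        self.boruta_max_iter = boruta_max_iter
        self.boruta_alpha = boruta_alpha
        self.boruta_trees = boruta_trees
        self.n_estimators = n_estimators
        self.min_top_k = min_top_k
        self.seed = seed
        self.artifacts: dict = {}

    @classmethod
    def from_cohort(cls, cohort, *, seed: int = 0, **kwargs) -> "ChemoResponseModel":
        """Build the model straight from a cohort bundle (synthetic or read
        from files), running deconvolution, scoring, copy-number signature
        extraction and rule flags along the way."""
        fm, artifacts = engineer_features(
            cohort.expression, cohort.segments, cohort.variants,
            cohort.clinical, cohort.pathogen_counts, seed=seed)
        model = cls(fm, seed=seed, **kwargs)
        model.artifacts = artifacts
        return model

    def fit(self, allow_tentative: bool = True) -> "ChemoResponseResults":
        fm = self.features
        train_ids, test_ids = train_test_split(
            fm.sample_ids, test_size=self.test_fraction,
            stratify=fm.y_binary,
            random_state=child_seed(self.seed, "split"))
        fm_train = fm.subset_samples(train_ids)
        fm_test = fm.subset_samples(test_ids)
        decision = boruta_select(
            fm_train, max_iter=self.boruta_max_iter, alpha=self.boruta_alpha,
            seed=self.seed, n_estimators=self.boruta_trees)
        trained, report = train_and_evaluate(
            fm_train, fm_test, decision=decision, seed=self.seed,
            n_estimators=self.n_estimators, allow_tentative=allow_tentative)
        tree = distill_tree(trained, fm_test, fm_train,
                            min_top_k=min(self.min_top_k, len(trained.features)))
        return ChemoResponseResults(
            model=self, decision=decision, trained=trained, test_report=report,
            tree=tree, train_ids=list(train_ids), test_ids=list(test_ids))


@dataclass
class ChemoResponseResults:
    """Fitted estimates, diagnostics and the distilled tree."""

    model: ChemoResponseModel
    decision: FeatureDecision
    trained: TrainedModel
    test_report: EvaluationReport
    tree: RepresentativeTree
    train_ids: list[str]
    test_ids: list[str]

    @property
    def auc_train_oob(self) -> float:
        return self.trained.oob_auc

    @property
    def auc_test(self) -> float:
        return self.test_report.auc

    @property
    def accuracy_test(self) -> float:
        return self.test_report.accuracy

    @property
    def selected_features(self) -> list[str]:
        return self.trained.features

    def predict_scores(self, fm: FeatureMatrix) -> pd.Series:
        return pd.Series(self.trained.scores(fm.X), index=fm.sample_ids,
                         name="score")

    def external_validate(self, fm_external: FeatureMatrix) -> dict:
        return external_validate(self.trained, fm_external)

    def summary(self) -> str:
        d = self.decision
        lines = [
            "Chemotherapy response model",
            "=" * 60,
            f"samples (train/test):      {len(self.train_ids)}/{len(self.test_ids)}",
            f"features assembled:        {len(self.model.features.feature_names)}",
            f"Confirmed / Tentative / Rejected: "
            f"{(d.status == 'Confirmed').sum()} / "
            f"{(d.status == 'Tentative').sum()} / "
            f"{(d.status == 'Rejected').sum()}",
            f"selection iterations:      {d.n_iterations}",
            f"ensemble trees:            {self.model.n_estimators}",
            f"AUC (train, out-of-bag):   {self.auc_train_oob:.3f}",
            f"AUC (held-out test):       {self.auc_test:.3f}",
            f"accuracy (held-out test):  {self.accuracy_test:.3f}",
            f"distilled tree fidelity:   {self.tree.fidelity:.3f}",
            f"tree features used:        {', '.join(self.tree.features_used)}",
            "-" * 60,
            "top features by ensemble importance:",
        ]
        for name, imp in self.trained.importances.head(10).items():
            lines.append(f"  {name:<40s} {imp:.4f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the held-out evaluation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.test_report.roc["fpr"], self.test_report.roc["tpr"],
                label=f"test AUC = {self.auc_test:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        return ax

    def to_model_card(self) -> dict:
        return {
            "n_train": len(self.train_ids),
            "n_test": len(self.test_ids),
            "seed": self.model.seed,
            "test_fraction": self.model.test_fraction,
            "boruta": {
                "max_iter": self.model.boruta_max_iter,
                "alpha": self.model.boruta_alpha,
                "n_iterations": self.decision.n_iterations,
                "confirmed": self.decision.confirmed,
                "tentative": self.decision.tentative,
            },
            "ensemble": {
                "n_estimators": self.model.n_estimators,
                "features": self.selected_features,
            },
            "auc_train_oob": self.auc_train_oob,
            "auc_test": self.auc_test,
            "accuracy_test": self.accuracy_test,
            "tree": {
                "fidelity": self.tree.fidelity,
                "features_used": self.tree.features_used,
            },
        }

    def save_model_card(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_model_card(), fh, indent=1, sort_keys=True)
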