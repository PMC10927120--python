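"""Same-domain pair probability model.

Two residues of a predicted model are scored for co-membership in a domain
from four pairwise quantities: C-alpha distance, symmetrized PAE, and the
numbers of sequence-profile and structure-alignment hits covering both
residues. A logistic regression on fixed feature transforms converts these
into a probability; the weights are fitted on labelled pairs drawn from the
synthetic benchmark and persisted with the run manifest.

Feature transforms (fixed, stored with the model):
    distance  -> min(d, 40) / 40
    PAE       -> min(pae, 31.75) / 31.75
    counts    -> log1p(count)
"""

from __future__ import annotations

import json
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .simulate import PAE_MAX, Block, SyntheticSpec, generate_hits, generate_model, make_reference_catalog
from .types import HomologyHit, PairFeatures, PredictedModel

D_CAP = 40.0

FEATURE_NAMES = ("d_ca", "pae_sym", "n_shared_seq", "n_shared_str")


def transform_features(X: np.ndarray) -> np.ndarray:
    """Apply the fixed transforms to raw feature columns (d, pae, nseq, nstr)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature value")
    Z = np.empty_like(X)
    Z[:, 0] = np.minimum(X[:, 0], D_CAP) / D_CAP
    Z[:, 1] = np.minimum(X[:, 1], PAE_MAX) / PAE_MAX
    Z[:, 2] = np.log1p(X[:, 2])
    Z[:, 3] = np.log1p(X[:, 3])
    return Z


def pair_feature_matrices(model: PredictedModel, hits: Sequence[HomologyHit]) -> dict:
    """All four pairwise feature matrices (n x n) for one model."""
    n = model.n_residues
    d = cdist(model.ca_coords, model.ca_coords)
    pae_sym = model.pae_sym()
    n_seq = np.zeros((n, n))
    n_str = np.zeros((n, n))
    for h in hits:
        ind = h.query_range.to_mask(n).astype(float)
        outer = np.outer(ind, ind)
        if h.source == "sequence_profile":
            n_seq += outer
        else:
            n_str += outer
    return {"d_ca": d, "pae_sym": pae_sym, "n_shared_seq": n_seq, "n_shared_str": n_str}


def compute_pair_features(
    model: PredictedModel, hits: Sequence[HomologyHit], i: int, j: int
) -> PairFeatures:
    """Features for one residue pair (1-based indices); symmetric in (i, j)."""
    n = model.n_residues
    if not (1 <= i <= n and 1 <= j <= n):
        raise IndexError(f"residue indices ({i}, {j}) outside 1..{n}")
    a, b = i - 1, j - 1
    d = float(np.linalg.norm(model.ca_coords[a] - model.ca_coords[b]))
    if model.pae is None:
        raise ValueError("PAE required")
    pae = 0.5 * (model.pae[a, b] + model.pae[b, a])
    nseq = nstr = 0
    for h in hits:
        res = h.query_range.residue_set()
        if i in res and j in res:
            if h.source == "sequence_profile":
                nseq += 1
            else:
                nstr += 1
    return PairFeatures(d_ca=d, pae_sym=float(pae), n_shared_seq=nseq, n_shared_str=nstr)


class PairDomainClassifier(BaseEstimator, ClassifierMixin):
    """Logistic same-domain classifier over residue-pair features.

    Parameters
    ----------
    C : float
        Inverse L2 regularization strength passed to the logistic fit.
    max_iter : int
        Solver iteration cap.
    random_state : int
        Kept for sklearn compatibility; the lbfgs solve is deterministic.

    Attributes
    ----------
    weights_ : ndarray of shape (5,)
        (w0, w_d, w_pae, w_seq, w_str) on the transformed feature scale.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 500, random_state: int = 0):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must be (n_pairs, 4): d_ca, pae_sym, n_seq, n_str")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both pair classes")
        Z = transform_features(X)
        lr = LogisticRegression(
            C=self.C, solver="lbfgs", max_iter=self.max_iter,
            random_state=self.random_state,
        )
        lr.fit(Z, y)
        self.weights_ = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        self.classes_ = classes
        self.n_features_in_ = 4
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        Z = transform_features(np.asarray(X, dtype=float))
        return self.weights_[0] + Z @ self.weights_[1:]

    def predict_proba(self, X) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.0).astype(int)

    # -- probability matrix over a whole model (vectorized) -----------------

    def probability_matrix(self, model: PredictedModel,
                           hits: Sequence[HomologyHit]) -> np.ndarray:
        """P(same domain) for every residue pair of ``model`` (n x n)."""
        check_is_fitted(self, "weights_")
        f = pair_feature_matrices(model, hits)
        w0, wd, wp, ws, wt = self.weights_
        z = (
            w0
            + wd * (np.minimum(f["d_ca"], D_CAP) / D_CAP)
            + wp * (np.minimum(f["pae_sym"], PAE_MAX) / PAE_MAX)
            + ws * np.log1p(f["n_shared_seq"])
            + wt * np.log1p(f["n_shared_str"])
        )
        return 1.0 / (1.0 + np.exp(-z))

    # -- persistence ---------------------------------------------------------

    def to_json(self, path=None) -> str:
        check_is_fitted(self, "weights_")
        payload = json.dumps({
            "weights": [float(w) for w in self.weights_],
            "features": list(FEATURE_NAMES),
            "transforms": {"d_ca": f"min(d,{D_CAP})/{D_CAP}",
                           "pae_sym": f"min(pae,{PAE_MAX})/{PAE_MAX}",
                           "counts": "log1p"},
            "params": {"C": self.C, "max_iter": self.max_iter},
        }, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "PairDomainClassifier":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        est = cls(**data.get("params", {}))
        est.weights_ = np.asarray(data["weights"], dtype=float)
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = 4
        return est


def fit_pair_model(training_pairs, reg: float = 1.0, seed: int = 0) -> PairDomainClassifier:
    """Fit from a list of (PairFeatures, same_domain_label) tuples."""
    X = np.array([f.as_array() for f, _ in training_pairs])
    y = np.array([int(lab) for _, lab in training_pairs])
    return PairDomainClassifier(C=1.0 / reg, random_state=seed).fit(X, y)


def pair_probability(model: PairDomainClassifier, f: PairFeatures) -> float:
    """Probability that the two residues of ``f`` share a domain."""
    return float(model.predict_proba(f.as_array()[None, :])[0, 1])


# ---------------------------------------------------------------------------
# synthetic benchmark for fitting / evaluating the pair model


def benchmark_pairs(
    seed: int = 1,
    n_models: int = 8,
    pairs_per_class: int = 1500,
) -> Tuple[np.ndarray, np.ndarray]:
    """Labelled residue pairs from two-domain synthetic chains.

    Positive pairs lie within one true domain; negative pairs span two
    different domains of the same chain. Pairs touching linkers/tails are not
    sampled — the flexibility filter removes those residues before pairing.
    About a third of benchmark domains carry no reference hits (domains exist
    without ascertainable homology), so the fit cannot treat shared hit
    membership as a necessary condition for co-membership.
    """
    rng = np.random.default_rng(seed)
    catalog = make_reference_catalog(6, seed=int(rng.integers(2**31)))
    groups = catalog.h_groups
    X_rows, y_rows = [], []
    per_model_pos = pairs_per_class // n_models
    per_model_neg = pairs_per_class // n_models
    for mi in range(n_models):
        scenarios = ["unassigned" if rng.random() < 1 / 3 else "assigned"
                     for _ in range(2)]
        blocks = [
            Block("domain", 60, group_id=str(rng.choice(groups)),
                  geometry=("helix_bundle", "sheet_sandwich", "mixed")[mi % 3],
                  scenario=scenarios[0]),
            Block("linker", 15),
            Block("domain", 60, group_id=str(rng.choice(groups)),
                  geometry=("sheet_sandwich", "mixed", "helix_bundle")[mi % 3],
                  scenario=scenarios[1]),
        ]
        spec = SyntheticSpec(blocks=blocks, seed=int(rng.integers(2**31)),
                             model_id=f"BM{mi:03d}")
        model, truth = generate_model(spec)
        hits = generate_hits(truth, catalog, seed=int(rng.integers(2**31)))
        f = pair_feature_matrices(model, hits)
        dom1 = np.arange(0, 60)
        dom2 = np.arange(75, 135)
        for _ in range(per_model_pos):
            dom = dom1 if rng.random() < 0.5 else dom2
            i, j = rng.choice(dom, size=2, replace=False)
            X_rows.append([f["d_ca"][i, j], f["pae_sym"][i, j],
                           f["n_shared_seq"][i, j], f["n_shared_str"][i, j]])
            y_rows.append(1)
        for _ in range(per_model_neg):
            i = int(rng.choice(dom1))
            j = int(rng.choice(dom2))
            X_rows.append([f["d_ca"][i, j], f["pae_sym"][i, j],
                           f["n_shared_seq"][i, j], f["n_shared_str"][i, j]])
            y_rows.append(0)
    return np.array(X_rows), np.array(y_rows)


def default_pair_model(seed: int = 1) -> PairDomainClassifier:
    """Fit the pair model on the synthetic benchmark (deterministic per seed)."""
    X, y = benchmark_pairs(seed=seed)
    return PairDomainClassifier(random_state=seed).fit(X, y)
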