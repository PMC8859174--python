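"""Log-linear thymic-selection model over CDR3 features.

Selection is modelled SONIA-style: each amino-acid clonotype sigma carries a
selection factor

    Q(sigma) = exp( sum_{f in features(sigma)} lambda_f  -  logZ )

over feature classes {CDR3 length, (amino acid, position from left),
(amino acid, position from right), V gene, J gene}, and the post-selection
probability is P_POST(sigma) = Q(sigma) * P_GEN(sigma).  Fitting maximizes
the mean log selection factor of an observed repertoire under the constraint
that Q has mean 1 over a baseline sample drawn from the generative model
(equivalently, logZ is the log of the baseline's mean exp-score).  The
objective is concave; it is ascended with L-BFGS and the gradient max-norm
is checked at the solution.

The P_GEN:P_POST ratio is written "1:x" with x = P_POST/P_GEN; small x means
the clone is easily generated but rarely survives selection.  Clones are
binned at x = 0.1 and x = 1e-4 (half-open, boundary to the upper class);
the "rare" bin (x < 1e-4) flags putative escapees of thymic negative
selection, and log10(P_POST) < -10 is reported alongside as a separate
co-criterion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, sparse

from .core import ClonotypeKey
from .vdj import GenerativeModel, pgen_aa, sample_productive
from Bio.Seq import Seq

MAX_POSITIONAL = 12  # positional features truncated this far from each end

NOT_RARE = "not_rare"
INTERMEDIATE = "intermediate"
RARE = "rare"


def featurize(key: ClonotypeKey) -> frozenset[str]:
    """Feature set of a clonotype: length, V, J and positional AA features.

    Exactly one length feature, one V, one J, and two positional features per
    CDR3 residue (left- and right-anchored, 1-based, truncated at
    ``MAX_POSITIONAL`` positions from each end).
    """
    aa = key.cdr3_aa
    n = len(aa)
    feats = {f"len:{n}", f"v:{key.v_gene}", f"j:{key.j_gene}"}
    for i, a in enumerate(aa):
        left = i + 1
        right = n - i
        if left <= MAX_POSITIONAL:
            feats.add(f"l:{left}:{a}")
        if right <= MAX_POSITIONAL:
            feats.add(f"r:{right}:{a}")
    return frozenset(feats)


@dataclass
class SelectionModel:
    """Fitted selection factors: feature -> lambda weight, plus logZ."""

    weights: dict[str, float] = field(default_factory=dict)
    log_z: float = 0.0
    fit_info: dict = field(default_factory=dict)

    def score(self, key: ClonotypeKey) -> float:
        """Sum of lambda over the clonotype's features (unknown features -> 0)."""
        return sum(self.weights.get(f, 0.0) for f in featurize(key))

    def q(self, key: ClonotypeKey) -> float:
        """Selection factor Q(sigma) = exp(score - logZ); always positive."""
        return float(np.exp(self.score(key) - self.log_z))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"weights": self.weights, "log_z": self.log_z, "fit_info": self.fit_info},
                indent=1,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionModel":
        d = json.loads(Path(path).read_text())
        return cls(weights=d["weights"], log_z=d["log_z"], fit_info=d.get("fit_info", {}))


@dataclass
class ProbabilityAnnotation:
    """Generation/selection probabilities and the ratio-based rarity bin."""

    key: ClonotypeKey
    pgen: float
    ppost: float
    q_ratio: float
    bin: str
    escapee: bool
    low_ppost: bool  # log10(ppost) < -10, the observed co-criterion
    ungeneratable: bool = False


def ratio_bin(pgen: float, ppost: float) -> str:
    """Bin the selection ratio x = P_POST/P_GEN at 0.1 and 1e-4.

    Half-open bins, boundary to the upper class: x >= 0.1 -> not_rare;
    1e-4 <= x < 0.1 -> intermediate; x < 1e-4 -> rare.
    """
    if pgen <= 0:
        raise ValueError("ratio_bin requires pgen > 0")
    r = ppost / pgen
    if r >= 0.1:
        return NOT_RARE
    if r >= 1e-4:
        return INTERMEDIATE
    return RARE


def ppost(
    model: SelectionModel, gen: GenerativeModel, key: ClonotypeKey
) -> ProbabilityAnnotation:
    """Annotate one clonotype with P_GEN, P_POST = Q * P_GEN, and its bin.

    P_GEN is the amino-acid generation probability restricted to the
    clonotype's V and J genes (keys carry V/J).  A clonotype the model cannot
    generate is annotated with both probabilities 0 and flagged.
    """
    pg = pgen_aa(gen, key.cdr3_aa, v_gene=key.v_gene, j_gene=key.j_gene)
    if pg <= 0:
        return ProbabilityAnnotation(
            key, 0.0, 0.0, 0.0, NOT_RARE, escapee=False, low_ppost=False, ungeneratable=True
        )
    pp = model.q(key) * pg
    b = ratio_bin(pg, pp)
    return ProbabilityAnnotation(
        key,
        pg,
        pp,
        pp / pg,
        b,
        escapee=(b == RARE),
        low_ppost=bool(pp > 0 and np.log10(pp) < -10),
    )


def flag_escapees(annotations: Sequence[ProbabilityAnnotation]) -> list[ProbabilityAnnotation]:
    """Annotations in the rare bin (putative thymic-selection escapees).

    The log10(P_POST) < -10 co-criterion is carried on each annotation's
    ``low_ppost`` field rather than filtering on it.
    """
    return [a for a in annotations if a.bin == RARE]


# ---------------------------------------------------------------------------
# Fitting


def _feature_matrix(
    keys: Sequence[ClonotypeKey], feat_index: dict[str, int]
) -> sparse.csr_matrix:
    rows, cols = [], []
    for i, key in enumerate(keys):
        for f in featurize(key):
            j = feat_index.get(f)
            if j is not None:
                rows.append(i)
                cols.append(j)
    data = np.ones(len(rows))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(keys), len(feat_index))
    )


def fit_selection(
    gen: GenerativeModel,
    observed: Sequence[ClonotypeKey],
    baseline_size: int,
    l2: float = 0.02,
    rng_seed: int | np.random.Generator = 0,
    baseline: Sequence[ClonotypeKey] | None = None,
    grad_tol: float = 1e-4,
    max_iter: int = 10_000,
) -> SelectionModel:
    """Fit selection factors from an observed repertoire.

    Maximizes mean_observed[log Q] subject to E_baseline[Q] = 1, i.e.
    minimizes the convex loss  -mean_obs(X lambda) + log mean_base(exp(X
    lambda)) + l2 * ||lambda||^2,  where the baseline is ``baseline_size``
    productive junctions sampled from ``gen`` (or supplied explicitly).
    Features absent from both samples are pinned to 0 and reported in
    ``fit_info``; the default ridge penalty (l2 = 0.02) keeps weights of
    rarely observed features near zero.  Deterministic given the seed.
    """
    if not observed:
        raise ValueError("observed repertoire must be non-empty")
    rng = (
        np.random.default_rng(rng_seed)
        if not isinstance(rng_seed, np.random.Generator)
        else rng_seed
    )
    if baseline is None:
        trips = sample_productive(gen, baseline_size, rng)
        baseline = [
            ClonotypeKey(v, j, str(Seq(nt).translate())) for v, j, nt in trips
        ]

    feats = sorted(
        set().union(*(featurize(k) for k in observed))
        | set().union(*(featurize(k) for k in baseline))
    )
    feat_index = {f: i for i, f in enumerate(feats)}
    x_obs = _feature_matrix(observed, feat_index)
    x_base = _feature_matrix(baseline, feat_index)
    mean_obs = np.asarray(x_obs.mean(axis=0)).ravel()
    n_base = x_base.shape[0]

    def loss_grad(lam: np.ndarray) -> tuple[float, np.ndarray]:
        s = x_base @ lam
        smax = s.max()
        w = np.exp(s - smax)
        zbar = w.sum() / n_base
        loss = -float(mean_obs @ lam) + float(np.log(zbar) + smax) + l2 * float(lam @ lam)
        base_mean = np.asarray((x_base.T @ (w / w.sum()))).ravel()
        grad = -mean_obs + base_mean + 2.0 * l2 * lam
        return loss, grad

    lam0 = np.zeros(len(feats))
    res = optimize.minimize(
        loss_grad,
        lam0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": grad_tol / 10},
    )
    lam = res.x
    _, grad = loss_grad(lam)
    gnorm = float(np.abs(grad).max())
    if gnorm > grad_tol:
        warnings.warn(
            f"selection fit did not reach gradient max-norm {grad_tol} "
            f"(final {gnorm:.2e})",
            RuntimeWarning,
        )
    s_base = x_base @ lam
    log_z = float(np.log(np.mean(np.exp(s_base - s_base.max()))) + s_base.max())
    return SelectionModel(
        weights={f: float(lam[i]) for f, i in feat_index.items()},
        log_z=log_z,
        fit_info={
            "n_observed": len(observed),
            "n_baseline": n_base,
            "l2": l2,
            "grad_max_norm": gnorm,
            "converged": bool(gnorm <= grad_tol),
            "n_features": len(feats),
        },
    )


def renormalize_exact(
    model: SelectionModel,
    keys: Iterable[ClonotypeKey],
    pgens: Iterable[float],
) -> SelectionModel:
    """Set logZ so that sum over the given key space of P_POST equals 1.

    For enumerable models this replaces the baseline-sample estimate of the
    normalization with the exact one over the full productive key space.
    """
    total = 0.0
    for key, pg in zip(keys, pgens):
        total += pg * np.exp(model.score(key))
    return SelectionModel(
        weights=dict(model.weights),
        log_z=float(np.log(total)),
        fit_info={**model.fit_info, "normalization": "exact"},
    )
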