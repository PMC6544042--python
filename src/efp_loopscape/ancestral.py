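"""Maximum-likelihood ancestral state reconstruction under the Mk model.

The Mk model is a continuous-time Markov chain over k discrete character
states on a rooted phylogeny. Three parameterisations are supported:

* ER  — equal rates, one parameter mu (off-diagonals all mu);
* SYM — symmetric exchange rates, k(k-1)/2 parameters;
* ARD — all rates different, k(k-1) parameters.

Likelihoods are computed with Felsenstein's pruning algorithm using
per-node rescaling to prevent underflow; marginal per-node posteriors come
from the standard up-pass (partial likelihoods) / down-pass (outside
probabilities) combination. The API follows the model/results convention:
:class:`MkAncestral` is built from a tree plus observed tip states, and
``fit()`` returns a :class:`MkAncestralResults` with the rate estimates,
maximized log-likelihood, per-node posteriors and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

__all__ = [
    "MkModel",
    "MkAncestral",
    "MkAncestralResults",
    "AncestralReconstruction",
    "mk_log_likelihood",
    "fit_mk_rate",
    "marginal_ancestral_states",
    "MISSING",
]

MISSING = "?"

_FORMS = ("ER", "SYM", "ARD")


def _n_params(form: str, k: int) -> int:
    if form == "ER":
        return 1
    if form == "SYM":
        return k * (k - 1) // 2
    if form == "ARD":
        return k * (k - 1)
    raise ValueError(f"unknown model form {form!r}; expected one of {_FORMS}")


@dataclass
class MkModel:
    """A (fitted or fixed) Mk substitution model.

    ``rates`` holds the free parameters in canonical order: ER — (mu,);
    SYM — upper-triangle (i<j) row-major; ARD — off-diagonal row-major.
    """

    states: tuple
    form: str = "ER"
    rates: np.ndarray = None
    root_prior: np.ndarray = None
    log_likelihood: Optional[float] = None

    def __post_init__(self):
        self.states = tuple(self.states)
        k = len(self.states)
        if k < 2:
            raise ValueError("need at least 2 states")
        if self.form not in _FORMS:
            raise ValueError(f"unknown model form {self.form!r}")
        if self.rates is None:
            self.rates = np.ones(_n_params(self.form, k))
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if self.rates.shape != (_n_params(self.form, k),):
            raise ValueError(f"{self.form} over {k} states needs {_n_params(self.form, k)} rates")
        if (self.rates <= 0).any():
            raise ValueError("rates must be > 0")
        if self.root_prior is None:
            self.root_prior = np.full(k, 1.0 / k)
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        if self.root_prior.shape != (k,) or abs(self.root_prior.sum() - 1.0) > 1e-9:
            raise ValueError("root prior must be a distribution over the states")

    @property
    def k(self) -> int:
        return len(self.states)

    def rate_matrix(self) -> np.ndarray:
        k = self.k
        q = np.zeros((k, k))
        if self.form == "ER":
            q[:] = self.rates[0]
        elif self.form == "SYM":
            idx = 0
            for i in range(k):
                for j in range(i + 1, k):
                    q[i, j] = q[j, i] = self.rates[idx]
                    idx += 1
        else:  # ARD
            idx = 0
            for i in range(k):
                for j in range(k):
                    if i != j:
                        q[i, j] = self.rates[idx]
                        idx += 1
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t); closed form for ER, eigendecomposition for SYM."""
        k = self.k
        if t == 0.0:
            return np.eye(k)
        if self.form == "ER":
            mu = self.rates[0]
            e = np.exp(-k * mu * t)
            p = np.full((k, k), (1.0 - e) / k)
            np.fill_diagonal(p, 1.0 / k + (k - 1) / k * e)
            return p
        q = self.rate_matrix()
        if self.form == "SYM":
            w, v = np.linalg.eigh(q)
            p = (v * np.exp(w * t)) @ v.T
        else:
            p = expm(q * t)
        p = np.clip(p.real, 0.0, None)
        rows = p.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        return p / rows


class MkAncestral:
    """Mk ancestral-state model for one character on a rooted tree.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with branch lengths. Internal nodes without labels are
        labelled in preorder.
    tip_states : mapping
        Leaf label -> observed state; ``"?"`` marks missing data. Every leaf
        must appear (use ``"?"`` explicitly for unobserved leaves).
    states : sequence, optional
        Character alphabet; defaults to the sorted observed states.
    form : {"ER", "SYM", "ARD"}
    root_prior : array, optional
        Distribution over states at the root; default uniform.
    """

    def __init__(self, tree, tip_states, states=None, form="ER", root_prior=None):
        if not tree.is_rooted:
            raise ValueError("Mk reconstruction requires a rooted tree")
        self.tree = tree
        self.form = form
        observed = {}
        leaf_labels = []
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            leaf_labels.append(label)
            if label not in tip_states:
                raise ValueError(f"leaf {label!r} absent from the state map (use '?' for missing)")
            observed[label] = tip_states[label]
        if all(v == MISSING for v in observed.values()):
            raise ValueError("all leaves are missing")
        if states is None:
            states = sorted({v for v in observed.values() if v != MISSING})
        self.states = tuple(states)
        bad = {v for v in observed.values() if v != MISSING and v not in self.states}
        if bad:
            raise ValueError(f"observed states outside the alphabet: {sorted(bad)}")
        self.tip_states = observed
        self.k = len(self.states)
        if self.k < 2:
            raise ValueError("need at least 2 states in the alphabet")
        self.root_prior = (
            np.full(self.k, 1.0 / self.k) if root_prior is None else np.asarray(root_prior, dtype=float)
        )

        n_internal = 0
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and not node.label:
                n_internal += 1
                node.label = f"N{n_internal:04d}"
            if node.parent_node is not None and node.edge.length is None:
                raise ValueError("tree has a branch without a length")
        self._postorder = list(tree.postorder_node_iter())

    # -- likelihood machinery ------------------------------------------------

    def _leaf_partial(self, label) -> np.ndarray:
        state = self.tip_states[label]
        if state == MISSING:
            return np.ones(self.k)
        vec = np.zeros(self.k)
        vec[self.states.index(state)] = 1.0
        return vec

    def _model(self, rates) -> MkModel:
        return MkModel(states=self.states, form=self.form, rates=rates, root_prior=self.root_prior)

    def _prune(self, model: MkModel):
        """Up-pass. Returns (partials, child_contribs, log_scale)."""
        partials: dict = {}
        contribs: dict = {}
        log_scale = 0.0
        for node in self._postorder:
            if node.is_leaf():
                partials[id(node)] = self._leaf_partial(node.taxon.label)
                continue
            vec = np.ones(self.k)
            for child in node.child_nodes():
                p = model.transition_matrix(float(child.edge.length or 0.0))
                contrib = p @ partials[id(child)]
                contribs[id(child)] = contrib
                vec = vec * contrib
            top = vec.max()
            if top <= 0.0:
                return partials, contribs, -np.inf
            vec = vec / top
            log_scale += np.log(top)
            partials[id(node)] = vec
        return partials, contribs, log_scale

    def loglike(self, rates) -> float:
        """Log-likelihood of the tip data under the given rate parameters."""
        model = self._model(rates)
        partials, _, log_scale = self._prune(model)
        if not np.isfinite(log_scale):
            return -np.inf
        root = self._postorder[-1]
        lik = float(self.root_prior @ partials[id(root)])
        if lik <= 0.0:
            return -np.inf
        return float(np.log(lik) + log_scale)

    def _posteriors(self, model: MkModel) -> pd.DataFrame:
        partials, contribs, _ = self._prune(model)
        root = self._postorder[-1]
        outside: dict = {id(root): self.root_prior.copy()}
        rows = {}
        for node in reversed(self._postorder):  # preorder
            post = outside[id(node)] * partials[id(node)]
            total = post.sum()
            if total <= 0:
                post = np.full(self.k, 1.0 / self.k)
            else:
                post = post / total
            label = node.taxon.label if node.is_leaf() else node.label
            rows[label] = post
            for child in node.child_nodes():
                sib = outside[id(node)].copy()
                for other in node.child_nodes():
                    if other is not child:
                        sib = sib * contribs[id(other)]
                p = model.transition_matrix(float(child.edge.length or 0.0))
                outside[id(child)] = p.T @ sib
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(self.states))

    # -- fitting -------------------------------------------------------------

    def fit(self, bounds=(1e-8, 1e3), tol=1e-9) -> "MkAncestralResults":
        """Maximize the likelihood over the rate parameters.

        ER uses bounded scalar optimization on mu; SYM/ARD use L-BFGS-B in
        log-rate space from a deterministic start. Deterministic throughout.
        """
        n = _n_params(self.form, self.k)
        if n == 1:
            # optimize in log-rate space; a coarse grid scan brackets the
            # optimum first so the flat high-rate plateau cannot trap Brent
            lo, hi = np.log(bounds[0]), np.log(bounds[1])
            grid = np.linspace(lo, hi, 41)
            nll = lambda lg: -self.loglike([np.exp(lg)])
            values = [nll(g) for g in grid]
            i = int(np.argmin(values))
            bracket = (grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)])
            res = minimize_scalar(
                nll, bounds=bracket, method="bounded", options={"xatol": tol}
            )
            best = res.x if res.fun <= values[i] else grid[i]
            rates = np.array([np.exp(best)])
            llf = -min(res.fun, values[i])
        else:
            lb, ub = np.log(bounds[0]), np.log(bounds[1])

            def nll(logr):
                return -self.loglike(np.exp(logr))

            x0 = np.zeros(n)  # all rates 1
            opt = minimize(nll, x0, method="L-BFGS-B", bounds=[(lb, ub)] * n)
            rates = np.exp(opt.x)
            llf = -opt.fun
        model = self._model(rates)
        model.log_likelihood = float(llf)
        return MkAncestralResults(model=self, mk_model=model, llf=float(llf))

    def results_for(self, model: MkModel) -> "MkAncestralResults":
        """Results object for a fixed (not fitted) model."""
        llf = self.loglike(model.rates)
        return MkAncestralResults(model=self, mk_model=model, llf=float(llf))


@dataclass
class MkAncestralResults:
    """Fitted Mk reconstruction: rates, log-likelihood, node posteriors."""

    model: MkAncestral
    mk_model: MkModel
    llf: float
    _posteriors: pd.DataFrame = field(default=None, repr=False)

    @property
    def rates(self) -> np.ndarray:
        return self.mk_model.rates

    @property
    def states(self) -> tuple:
        return self.mk_model.states

    def ancestral_states(self) -> pd.DataFrame:
        """Marginal posterior state probabilities for every node (rows sum to 1)."""
        if self._posteriors is None:
            self._posteriors = self.model._posteriors(self.mk_model)
        return self._posteriors

    @property
    def root_posterior(self) -> pd.Series:
        root = self.model.tree.seed_node
        label = root.taxon.label if root.is_leaf() else root.label
        return self.ancestral_states().loc[label]

    def summarize_root(self) -> dict:
        post = self.root_posterior
        best = post.idxmax()
        return {
            "state": best,
            "probability": float(post[best]),
            "posterior": {s: float(post[s]) for s in post.index},
        }

    def summary(self) -> str:
        lines = [
            "Mk ancestral state reconstruction",
            "=" * 46,
            f"states:          {', '.join(self.states)}",
            f"model form:      {self.mk_model.form}",
            f"log-likelihood:  {self.llf:.6f}",
        ]
        if self.mk_model.form == "ER":
            lines.append(f"rate (mu):       {self.rates[0]:.6g}")
        else:
            lines.append(f"rates:           {np.array2string(self.rates, precision=4)}")
        root = self.summarize_root()
        lines.append(
            "root state:      "
            + ", ".join(f"P({s}) = {p:.4f}" for s, p in root["posterior"].items())
        )
        lines.append(f"most likely root state: {root['state']} ({root['probability']:.4f})")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        df = self.ancestral_states().copy()
        df.insert(0, "node", df.index)
        return df.reset_index(drop=True)


# spec-surface free functions -------------------------------------------------

AncestralReconstruction = MkAncestralResults


def mk_log_likelihood(tree, states, model: MkModel) -> float:
    """Pruning log-likelihood of leaf states under a fixed Mk model."""
    m = MkAncestral(tree, states, states=model.states, form=model.form, root_prior=model.root_prior)
    return m.loglike(model.rates)


def fit_mk_rate(tree, states, form: str = "ER", alphabet=None, root_prior=None,
                bounds=(1e-8, 1e3), tol=1e-9) -> MkModel:
    """ML rate estimation; returns the fitted MkModel (with log_likelihood)."""
    m = MkAncestral(tree, states, states=alphabet, form=form, root_prior=root_prior)
    return m.fit(bounds=bounds, tol=tol).mk_model


def marginal_ancestral_states(tree, states, model: MkModel) -> MkAncestralResults:
    """Marginal per-node posteriors under a fixed (e.g. fitted) model."""
    m = MkAncestral(tree, states, states=model.states, form=model.form, root_prior=model.root_prior)
    return m.results_for(model)
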