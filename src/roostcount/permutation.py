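"""Linear models with sequential sums of squares and permutation p-values.

Counts are modelled by ordinary least squares with treatment-coded factors;
each term's F statistic uses sequential (type-I) sums of squares in the
declared order.  p-values come from resampling rather than F-distribution
theory: for a single-term model the raw response is permuted; in models with
nuisance terms each term is tested by permuting the residuals of the model
without that term (Freedman-Lane), which preserves exchangeability under
the term's null.  The permutation p-value is

    p = (1 + #{F* >= F_obs}) / (n_perm + 1)

so it is floored at 1/(n_perm + 1); ties count as exceedances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DesignError

_FACTOR_DEFAULTS = {"roost", "month"}


@dataclass(frozen=True)
class Term:
    """One model term: a main effect or a ':'-joined interaction."""

    name: str
    kind: str  # "factor" | "covariate" | "interaction"

    @property
    def parts(self) -> tuple[str, ...]:
        return tuple(self.name.split(":"))


@dataclass(frozen=True)
class ModelSpec:
    """Response plus an ordered list of terms.

    ``kinds`` maps main-effect names to "factor" or "covariate"; unlisted
    names default to factor for roost/month-style labels and are otherwise
    inferred from the data column dtype at fit time.
    """

    response: str
    terms: tuple[Term, ...]

    @classmethod
    def build(
        cls, response: str, terms: list[str], kinds: dict[str, str] | None = None
    ) -> "ModelSpec":
        kinds = dict(kinds or {})
        seen: set[str] = set()
        built: list[Term] = []
        for name in terms:
            if name in seen:
                raise ValueError(f"duplicate term {name!r}")
            seen.add(name)
            if ":" in name:
                for part in name.split(":"):
                    if part not in seen:
                        raise ValueError(
                            f"interaction {name!r} references undeclared main effect {part!r}"
                        )
                built.append(Term(name, "interaction"))
            else:
                built.append(Term(name, kinds.get(name, "")))
        return cls(response=response, terms=tuple(built))

    @classmethod
    def from_formula(cls, formula: str, kinds: dict[str, str] | None = None) -> "ModelSpec":
        """Parse 'y ~ a + b', 'y ~ a * b' (main effects then interaction)."""
        lhs, rhs = (side.strip() for side in formula.split("~", 1))
        terms: list[str] = []
        for chunk in rhs.split("+"):
            chunk = chunk.strip()
            if "*" in chunk:
                parts = [p.strip() for p in chunk.split("*")]
                terms.extend(p for p in parts if p not in terms)
                terms.append(":".join(parts))
            elif chunk:
                terms.append(chunk)
        return cls.build(lhs, terms, kinds)


@dataclass(frozen=True)
class TermStat:
    name: str
    F: float
    df: tuple[int, int]
    ss: float
    p_perm: float | None = None


@dataclass(frozen=True)
class LinearModelFit:
    terms: tuple[TermStat, ...]
    r2: float
    rss: float
    df_resid: int
    n_obs: int
    coefficients: dict[str, float]

    def term(self, name: str) -> TermStat:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class PermutationResult:
    """Sequential-SS F statistics with permutation p-values."""

    terms: tuple[TermStat, ...]
    r2: float
    df_resid: int
    n_obs: int
    n_perm: int
    seed: int
    scheme: str
    coefficients: dict[str, float] = field(default_factory=dict)

    def term(self, name: str) -> TermStat:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def p_floor(self) -> float:
        return 1.0 / (self.n_perm + 1)


def _resolve_kind(term: Term, data: pd.DataFrame) -> str:
    if term.kind in ("factor", "covariate", "interaction"):
        return term.kind
    if term.name in _FACTOR_DEFAULTS:
        return "factor"
    return "covariate" if pd.api.types.is_numeric_dtype(data[term.name]) else "factor"


def _main_effect_block(
    name: str, kind: str, data: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    col = data[name]
    if kind == "factor":
        levels = sorted(pd.unique(col.astype(str)))
        if len(levels) < 2:
            raise DesignError(f"factor {name!r} has fewer than 2 observed levels")
        block = np.column_stack(
            [(col.astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]]
        )
        labels = [f"{name}[{lv}]" for lv in levels[1:]]
        return block, labels
    return col.to_numpy(dtype=float).reshape(-1, 1), [name]


def build_design(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[list[np.ndarray], list[list[str]], list[Term]]:
    """Treatment-coded design blocks, one per term, in declared order."""
    blocks: dict[str, tuple[np.ndarray, list[str]]] = {}
    out_blocks: list[np.ndarray] = []
    out_labels: list[list[str]] = []
    resolved: list[Term] = []
    for term in spec.terms:
        kind = _resolve_kind(term, data)
        if kind == "interaction":
            parts = term.parts
            sub_blocks, sub_labels = [], []
            for part in parts:
                if part not in blocks:
                    raise DesignError(f"interaction {term.name!r} lacks main effect {part!r}")
                sub_blocks.append(blocks[part][0])
                sub_labels.append(blocks[part][1])
            block = sub_blocks[0]
            labels = sub_labels[0]
            for b, ls in zip(sub_blocks[1:], sub_labels[1:]):
                block = np.einsum("ij,ik->ijk", block, b).reshape(len(data), -1)
                labels = [f"{l1}:{l2}" for l1 in labels for l2 in ls]
        else:
            block, labels = _main_effect_block(term.name, kind, data)
            blocks[term.name] = (block, labels)
        out_blocks.append(block)
        out_labels.append(labels)
        resolved.append(Term(term.name, kind))
    return out_blocks, out_labels, resolved


def _orth(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (SVD, numerical rank)."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    return u[:, s > tol]


class _SequentialDesign:
    """Nested orthonormal bases for intercept, +term1, +term1+term2, ..."""

    def __init__(self, blocks: list[np.ndarray], names: list[str], n: int):
        self.names = names
        ones = np.ones((n, 1))
        cum = ones
        self.bases: list[np.ndarray] = [_orth(ones)]
        self.df_terms: list[int] = []
        for block, name in zip(blocks, names):
            cum = np.hstack([cum, block])
            basis = _orth(cum)
            gained = basis.shape[1] - self.bases[-1].shape[1]
            if gained == 0:
                raise DesignError(
                    f"term {name!r} is aliased with preceding terms (adds no rank)"
                )
            self.df_terms.append(gained)
            self.bases.append(basis)
        self.n = n
        self.rank_full = self.bases[-1].shape[1]
        self.df_resid = n - self.rank_full
        if self.df_resid <= 0:
            raise DesignError("saturated design: no residual degrees of freedom")
        self.X_full = np.hstack([ones] + blocks)

    def term_F(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sequential F per term for each column of Y.

        Returns (F[k, b], sst[b], rss_full[b]).
        """
        Y = np.atleast_2d(Y.T).T  # ensure (n, B)
        total = np.sum(Y**2, axis=0)
        rss = np.array(
            [total - np.sum((Q.T @ Y) ** 2, axis=0) for Q in self.bases]
        )  # (n_models+1, B), rss[0] = about-the-mean SST
        ss_terms = rss[:-1] - rss[1:]
        rss_full = rss[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            mse = rss_full / self.df_resid
            F = (ss_terms / np.array(self.df_terms)[:, None]) / mse
        F = np.where(np.isfinite(F), F, 0.0)
        return F, rss[0], rss_full


def fit_linear_model(spec: ModelSpec, data: pd.DataFrame) -> LinearModelFit:
    """OLS fit with per-term sequential F, df and model r^2 (no p-values)."""
    data = data.reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values; drop them first")
    blocks, labels, _ = build_design(spec, data)
    design = _SequentialDesign(blocks, [t.name for t in spec.terms], len(y))
    F, sst, rss_full = design.term_F(y[:, None])
    F, sst, rss_full = F[:, 0], float(sst[0]), float(rss_full[0])
    total = float(np.sum(y**2))
    rss_seq = [total - float(np.sum((Q.T @ y) ** 2)) for Q in design.bases]
    ss_terms = [rss_seq[k] - rss_seq[k + 1] for k in range(len(design.df_terms))]
    r2 = 0.0 if sst <= 0 else 1.0 - rss_full / sst
    coefs, *_ = np.linalg.lstsq(design.X_full, y, rcond=None)
    names = ["(intercept)"] + [lab for ls in labels for lab in ls]
    stats = tuple(
        TermStat(
            name=t.name,
            F=float(F[k]) if sst > 0 else 0.0,
            df=(design.df_terms[k], design.df_resid),
            ss=ss_terms[k],
        )
        for k, t in enumerate(spec.terms)
    )
    return LinearModelFit(
        terms=stats,
        r2=max(0.0, min(1.0, r2)),
        rss=rss_full,
        df_resid=design.df_resid,
        n_obs=len(y),
        coefficients=dict(zip(names, map(float, coefs))),
    )


def _perm_pvalue(f_obs: float, f_star: np.ndarray, n_perm: int) -> float:
    eps = 1e-9 * max(1.0, abs(f_obs))
    return (1.0 + int(np.sum(f_star >= f_obs - eps))) / (n_perm + 1.0)


def permutation_test(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_perm: int = 4999,
    seed: int = 0,
    scheme: str = "auto",
) -> PermutationResult:
    """Per-term permutation p-values for a sequential-SS linear model.

    scheme "raw" permutes the response (appropriate for single-term models);
    "freedman-lane" permutes, for each term, the residuals of the model
    excluding that term.  "auto" picks raw for one term, Freedman-Lane
    otherwise.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if scheme == "auto":
        scheme = "raw" if len(spec.terms) == 1 else "freedman-lane"
    if scheme not in ("raw", "freedman-lane"):
        raise ValueError(f"unknown scheme {scheme!r}")
    fit = fit_linear_model(spec, data)
    data = data.reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)
    blocks, labels, _ = build_design(spec, data)
    design = _SequentialDesign(blocks, [t.name for t in spec.terms], len(y))
    rng = np.random.default_rng(seed)
    n = len(y)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    p_values: dict[str, float] = {}
    if scheme == "raw":
        Y = y[perms].T  # (n, n_perm)
        F_star, _, _ = design.term_F(Y)
        for k, t in enumerate(fit.terms):
            p_values[t.name] = _perm_pvalue(t.F, F_star[k], n_perm)
    else:
        ones = np.ones((n, 1))
        for k, t in enumerate(fit.terms):
            # nuisance space excludes the tested term and any interaction
            # containing it (which would absorb the very effect under test)
            tested_parts = set(spec.terms[k].parts)
            nuisance = [
                b for j, b in enumerate(blocks)
                if j != k and not tested_parts & set(spec.terms[j].parts)
            ]
            Qn = _orth(np.hstack([ones] + nuisance)) if nuisance else _orth(ones)
            fitted = Qn @ (Qn.T @ y)
            resid = y - fitted
            Y = fitted[:, None] + resid[perms].T
            F_star, _, _ = design.term_F(Y)
            p_values[t.name] = _perm_pvalue(t.F, F_star[k], n_perm)

    stats = tuple(
        TermStat(t.name, t.F, t.df, t.ss, p_perm=p_values[t.name]) for t in fit.terms
    )
    return PermutationResult(
        terms=stats,
        r2=fit.r2,
        df_resid=fit.df_resid,
        n_obs=fit.n_obs,
        n_perm=n_perm,
        seed=seed,
        scheme=scheme,
        coefficients=fit.coefficients,
    )


@dataclass(frozen=True)
class AncovaResult:
    """Final ANCOVA fit plus the parallelism (interaction) check."""

    final: PermutationResult
    interaction_name: str
    interaction_p: float
    parallel: bool

    @property
    def flag(self) -> str:
        return "parallel-slopes" if self.parallel else "non-parallel"


def ancova_with_parallelism(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 4999,
    seed: int = 0,
) -> AncovaResult:
    """ANCOVA with a preliminary slope-parallelism check.

    Fits the model including the factor x covariate interaction; if the
    interaction is non-significant at ``alpha`` it is dropped and the
    additive (parallel-slopes) model is returned, otherwise the interaction
    model stands.
    """
    inter = [t for t in spec.terms if ":" in t.name]
    if len(inter) != 1:
        raise DesignError("ancova_with_parallelism needs exactly one interaction term")
    inter_name = inter[0].name
    full = permutation_test(spec, data, n_perm=n_perm, seed=seed, scheme="freedman-lane")
    p_int = full.term(inter_name).p_perm
    if p_int >= alpha:
        reduced = ModelSpec(
            response=spec.response,
            terms=tuple(t for t in spec.terms if t.name != inter_name),
        )
        final = permutation_test(
            reduced, data, n_perm=n_perm, seed=seed, scheme="freedman-lane"
        )
        return AncovaResult(final=final, interaction_name=inter_name,
                            interaction_p=p_int, parallel=True)
    return AncovaResult(final=full, interaction_name=inter_name,
                        interaction_p=p_int, parallel=False)
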