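"""Network Perturbation Amplitude (NPA) scoring of expression profiles.

Given a two-layer model and a differential-expression profile, scoring runs
in three stages:

1. **Activity inference.** For each iNode ``x`` with signed signature
   ``T(x)``, the activity is the signed mean of the measured log2
   fold-changes: ``a(x) = mean_{g in T(x), measured} s_xg * beta_g``.
   A gene's sign ``s_xg`` says whether the gene goes up (+1) or down (-1)
   when the node is active, so a profile matching the signature yields a
   positive activity.

2. **Coefficient fit.** Node coefficients ``c`` minimise the quadratic
   consistency functional

   ``J(c) = sum_{(x->y), sign!=0} w_xy (c(y) - sigma_xy c(x))^2
            + lambda * sum_{anchored iNodes x} (c(x) - a(x))^2``

   i.e. a harmonic fit on the signed backbone anchored at inferred
   activities. The normal equations form one sparse symmetric
   positive-semidefinite system (a signed graph Laplacian plus anchor and
   ridge diagonals); connected components with no anchored iNode resolve
   to zero and are reported.

3. **Amplitude.** ``NPA = mean_x c(x)^2`` over the scoring-subgraph nodes.
   Activities that the backbone accommodates propagate into large
   coefficients and a large NPA; contradictions between activities and
   topology shrink the fit and the NPA.

The NPA is accompanied by a parametric-Monte-Carlo confidence interval
(gene-wise normal resampling of the profile) and two permutation
p-values: the *o* statistic permutes transcript-layer gene assignments
(specificity of the signatures) and the *k* statistic rewires
functional-layer edge targets (contribution of the backbone topology).
Both use add-one one-sided upper-tail p-values, so p is never 0.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import factorized, spsolve

from .network_model import CausalEdge, ModelError, TwoLayerModel

logger = logging.getLogger(__name__)


class ScoringError(RuntimeError):
    pass


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent named random substream derived from one top-level seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionProfile:
    """Per-gene log2 fold-change and optional variance for one contrast.

    ``data`` maps upper-cased gene ids to ``(beta, variance)``; a missing
    standard error is stored as zero variance.
    """

    data: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[float, float]] = {}
        for gene, (beta, var) in self.data.items():
            beta = float(beta)
            var = float(var)
            if not math.isfinite(beta):
                raise ModelError(f"non-finite log2 fold-change for gene {gene!r}")
            if var < 0 or not math.isfinite(var):
                raise ModelError(f"variance must be finite and >= 0 for gene {gene!r}")
            clean[gene.upper()] = (beta, var)
        self.data = clean

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.data

    def genes(self) -> set[str]:
        return set(self.data)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionProfile":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        if "gene_id" not in df.columns or "log2fc" not in df.columns:
            raise ModelError(f"expression TSV needs columns gene_id, log2fc[, se]; got {list(df.columns)}")
        has_se = "se" in df.columns
        data = {}
        for row in df.itertuples(index=False):
            var = float(row.se) ** 2 if has_se and pd.notna(row.se) else 0.0
            data[row.gene_id] = (float(row.log2fc), var)
        return cls(data)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene_id": g, "log2fc": b, "se": math.sqrt(v)}
            for g, (b, v) in sorted(self.data.items())
        ]
        pd.DataFrame(rows, columns=["gene_id", "log2fc", "se"]).to_csv(path, sep="\t", index=False)


@dataclass
class FitConfig:
    """Tunables of the fit and its companion statistics.

    anchor_weight -- weight lambda of the activity anchor terms (relative to
    unit edge weights); ridge -- small diagonal regulariser that pins
    unanchored components at zero; permutations -- draws for each of the o/k
    statistics; alpha -- significance level; ci_draws -- Monte-Carlo draws
    for the confidence interval; seed -- top-level seed fanned out into
    named substreams (ci/o/k).
    """

    anchor_weight: float = 1.0
    ridge: float = 1e-9
    permutations: int = 500
    alpha: float = 0.05
    ci_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.anchor_weight <= 0:
            raise ModelError("anchor_weight must be > 0")
        if self.permutations < 1:
            raise ModelError("permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ModelError("alpha must lie in (0, 1)")


@dataclass
class ActivityMap:
    """Inferred iNode activities with per-iNode measured-gene coverage."""

    values: dict[str, float]
    coverage: dict[str, tuple[int, int]]
    excluded: tuple[str, ...] = ()


@dataclass
class CoefficientMap:
    """Fitted coefficients over every scoring-subgraph node."""

    values: dict[str, float]
    unanchored_components: tuple[frozenset, ...] = ()


@dataclass
class ScoreResult:
    npa: float
    ci: tuple[float, float]
    p_o: float
    p_k: float
    coefficients: CoefficientMap
    contributions: dict[str, float] | None
    config: FitConfig
    activities: ActivityMap | None = None
    o_null: np.ndarray | None = field(default=None, repr=False)
    k_null: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# stage 1: activities
# ---------------------------------------------------------------------------


def infer_activities(model: TwoLayerModel, profile: ExpressionProfile) -> ActivityMap:
    """Signed-mean activity of each iNode over its measured signature genes.

    Unmeasured genes are skipped; iNodes with no measured gene are excluded
    and listed. If no iNode overlaps the profile at all, scoring cannot
    proceed.
    """
    if len(profile) == 0:
        raise ScoringError("empty expression profile")
    values: dict[str, float] = {}
    coverage: dict[str, tuple[int, int]] = {}
    excluded: list[str] = []
    for inode, signature in model.layer.signatures.items():
        measured = [(g, s) for g, s in signature if g in profile.data]
        coverage[inode] = (len(measured), len(signature))
        if not measured:
            excluded.append(inode)
            continue
        values[inode] = float(np.mean([s * profile.data[g][0] for g, s in measured]))
    if not values:
        raise ScoringError("profile does not overlap transcript layer: no iNode has a measured gene")
    if excluded:
        logger.info("excluded %d iNodes with no measured signature gene: %s", len(excluded), sorted(excluded))
    return ActivityMap(values=values, coverage=coverage, excluded=tuple(sorted(excluded)))


# ---------------------------------------------------------------------------
# stage 2: coefficient fit
# ---------------------------------------------------------------------------


def _edge_arrays(edges: Sequence[CausalEdge], index: Mapping[str, int]):
    src = np.fromiter((index[e.source] for e in edges), dtype=np.int64, count=len(edges))
    tgt = np.fromiter((index[e.target] for e in edges), dtype=np.int64, count=len(edges))
    sign = np.fromiter((e.sign for e in edges), dtype=np.float64, count=len(edges))
    weight = np.fromiter((e.weight for e in edges), dtype=np.float64, count=len(edges))
    return src, tgt, sign, weight


def _build_matrix(n: int, src, tgt, sign, weight, anchored_idx, lam: float, ridge: float) -> sp.csc_matrix:
    """Normal-equation matrix of J: signed Laplacian + anchor + ridge diagonals."""
    rows = np.concatenate([src, tgt, src, tgt])
    cols = np.concatenate([src, tgt, tgt, src])
    vals = np.concatenate([weight, weight, -weight * sign, -weight * sign])
    diag_rows = np.arange(n)
    anchor_diag = np.zeros(n)
    anchor_diag[anchored_idx] = lam
    rows = np.concatenate([rows, diag_rows])
    cols = np.concatenate([cols, diag_rows])
    vals = np.concatenate([vals, anchor_diag + ridge])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def _components(n: int, src, tgt) -> np.ndarray:
    adj = sp.coo_matrix((np.ones(len(src)), (src, tgt)), shape=(n, n))
    _, labels = sp.csgraph.connected_components(adj, directed=False)
    return labels


class _FixedTopologySolver:
    """Caches the factorised normal-equation matrix for repeated right-hand sides.

    The matrix depends on the backbone and on *which* iNodes are anchored,
    not on the activity values, so confidence-interval draws and
    transcript-layer permutations reuse one factorisation.
    """

    def __init__(self, model: TwoLayerModel, anchored_ids: Sequence[str], cfg: FitConfig):
        net = model.network
        self.node_ids = net.node_ids()
        self.index = {nid: i for i, nid in enumerate(self.node_ids)}
        self.n = len(self.node_ids)
        edges = net.scoring_edges()
        src, tgt, sign, weight = _edge_arrays(edges, self.index)
        self.anchored_ids = list(anchored_ids)
        self.anchored_idx = np.fromiter((self.index[i] for i in self.anchored_ids), dtype=np.int64,
                                        count=len(self.anchored_ids))
        self.lam = cfg.anchor_weight
        matrix = _build_matrix(self.n, src, tgt, sign, weight, self.anchored_idx, self.lam, cfg.ridge)
        try:
            self._solve = factorized(matrix)
        except RuntimeError as exc:  # pragma: no cover - cured by ridge in practice
            raise ScoringError(f"singular fit system: {exc}") from exc
        labels = _components(self.n, src, tgt)
        anchored_labels = set(labels[self.anchored_idx].tolist())
        self.unanchored_components = tuple(
            frozenset(self.node_ids[i] for i in np.flatnonzero(labels == lab))
            for lab in sorted(set(labels.tolist()) - anchored_labels)
        )

    def solve(self, activities: np.ndarray) -> np.ndarray:
        """Coefficients for anchor values aligned with ``anchored_ids``."""
        b = np.zeros(self.n)
        b[self.anchored_idx] = self.lam * activities
        c = self._solve(b)
        if not np.all(np.isfinite(c)):
            raise ScoringError(
                "fit produced non-finite coefficients; offending components: "
                f"{[sorted(comp) for comp in self.unanchored_components]}"
            )
        return c

    def npa(self, activities: np.ndarray) -> float:
        c = self.solve(activities)
        return float(np.mean(c**2))


def fit_coefficients(model: TwoLayerModel, act: ActivityMap, cfg: FitConfig | None = None) -> CoefficientMap:
    """Minimise J(c) over all scoring-subgraph nodes (sparse SPD solve)."""
    cfg = cfg or FitConfig()
    anchored = sorted(act.values)
    solver = _FixedTopologySolver(model, anchored, cfg)
    a = np.array([act.values[i] for i in anchored])
    c = solver.solve(a)
    return CoefficientMap(
        values=dict(zip(solver.node_ids, c.tolist())),
        unanchored_components=solver.unanchored_components,
    )


# ---------------------------------------------------------------------------
# stage 3: amplitude
# ---------------------------------------------------------------------------


def compute_npa(coeff: CoefficientMap | Mapping[str, float]) -> float:
    """NPA = mean of squared node coefficients over the scoring subgraph."""
    values = coeff.values if isinstance(coeff, CoefficientMap) else coeff
    c = np.fromiter(values.values(), dtype=float, count=len(values))
    if c.size == 0:
        return 0.0
    return float(np.mean(c**2))


def node_contributions(coeff: CoefficientMap | Mapping[str, float]) -> dict[str, float] | None:
    """Fraction c(x)^2 / sum c^2 per node; None when all coefficients are zero."""
    values = coeff.values if isinstance(coeff, CoefficientMap) else coeff
    total = sum(v * v for v in values.values())
    if total == 0:
        logger.info("all coefficients zero: contributions undefined")
        return None
    return {k: v * v / total for k, v in values.items()}


# ---------------------------------------------------------------------------
# companion statistics
# ---------------------------------------------------------------------------


def _measured_signatures(model: TwoLayerModel, profile: ExpressionProfile):
    """(inode, measured genes, signs) triples restricted to measured genes."""
    out = []
    for inode, signature in model.layer.signatures.items():
        genes = [g for g, _ in signature if g in profile.data]
        signs = np.array([s for g, s in signature if g in profile.data], dtype=float)
        if genes:
            out.append((inode, genes, signs))
    if not out:
        raise ScoringError("profile does not overlap transcript layer: no iNode has a measured gene")
    return out


def _observed_npa(model: TwoLayerModel, profile: ExpressionProfile, cfg: FitConfig) -> float:
    act = infer_activities(model, profile)
    return compute_npa(fit_coefficients(model, act, cfg))


def confidence_interval(
    model: TwoLayerModel, profile: ExpressionProfile, cfg: FitConfig
) -> tuple[float, float]:
    """Parametric Monte-Carlo CI of the NPA.

    Each draw perturbs every gene independently as normal(beta_g, v_g)
    (missing variances are zero) and rescores; the interval is the empirical
    (alpha/2, 1-alpha/2) quantile pair. Seeded via the ``ci`` substream.
    """
    if cfg.ci_draws < 2:
        raise ModelError("ci_draws must be >= 2")
    rng = substream(cfg.seed, "ci")
    sigs = _measured_signatures(model, profile)
    anchored = sorted(i for i, _, _ in sigs)
    solver = _FixedTopologySolver(model, anchored, cfg)
    order = {i: k for k, i in enumerate(anchored)}

    genes = sorted(profile.data)
    beta = np.array([profile.data[g][0] for g in genes])
    sd = np.sqrt([profile.data[g][1] for g in genes])
    gene_idx = {g: i for i, g in enumerate(genes)}
    sig_idx = [(order[inode], np.array([gene_idx[g] for g in gg]), ss) for inode, gg, ss in sigs]

    npas = np.empty(cfg.ci_draws)
    a = np.empty(len(anchored))
    for d in range(cfg.ci_draws):
        draw = beta + sd * rng.standard_normal(beta.size)
        for pos, idx, ss in sig_idx:
            a[pos] = np.mean(ss * draw[idx])
        npas[d] = solver.npa(a)
    lo, hi = np.quantile(npas, [cfg.alpha / 2, 1 - cfg.alpha / 2])
    return float(lo), float(hi)


def _pvalue(null: np.ndarray, observed: float, n: int) -> float:
    return float((1 + int(np.sum(null >= observed))) / (1 + n))


def o_statistic(
    model: TwoLayerModel, profile: ExpressionProfile, cfg: FitConfig
) -> tuple[float, np.ndarray]:
    """Transcript-layer permutation test.

    Each permutation redraws the gene endpoints of every transcript-layer
    edge without replacement from the measured gene universe, keeping
    per-iNode edge counts and signs; the model is rescored end to end.
    Returns the add-one upper-tail p-value and the permuted NPA values.
    """
    sigs = _measured_signatures(model, profile)
    genes = sorted(profile.data)
    universe_beta = np.array([profile.data[g][0] for g in genes])
    largest = max(len(model.layer.signatures[i]) for i in model.layer.signatures)
    if largest > len(genes):
        raise ScoringError(
            f"measured gene universe ({len(genes)}) smaller than the largest iNode signature ({largest})"
        )
    observed = _observed_npa(model, profile, cfg)

    anchored = sorted(model.layer.signatures)  # permuted genes are always measured
    sizes = [(i, len(model.layer.signatures[i]),
              np.array([s for _, s in model.layer.signatures[i]], dtype=float)) for i in anchored]
    solver = _FixedTopologySolver(model, anchored, cfg)
    rng = substream(cfg.seed, "o")
    null = np.empty(cfg.permutations)
    a = np.empty(len(anchored))
    n_universe = len(genes)
    for p in range(cfg.permutations):
        for pos, (inode, k, signs) in enumerate(sizes):
            idx = rng.choice(n_universe, size=k, replace=False)
            a[pos] = np.mean(signs * universe_beta[idx])
        null[p] = solver.npa(a)
    return _pvalue(null, observed, cfg.permutations), null


def k_statistic(
    model: TwoLayerModel, profile: ExpressionProfile, cfg: FitConfig
) -> tuple[float, np.ndarray]:
    """Functional-layer permutation test.

    Each permutation shuffles the target endpoints among the scoring-subgraph
    edges (sources, signs and weights stay with their edges); the transcript
    layer is untouched. Permutations creating self-loops are redrawn up to
    10 times, then accepted and logged.
    """
    net = model.network
    edges = net.scoring_edges()
    if len(edges) < 1:
        raise ScoringError("functional-layer permutation needs at least one scoring edge")
    act = infer_activities(model, profile)
    observed = compute_npa(fit_coefficients(model, act, cfg))

    node_ids = net.node_ids()
    index = {nid: i for i, nid in enumerate(node_ids)}
    src, tgt, sign, weight = _edge_arrays(edges, index)
    anchored = sorted(act.values)
    anchored_idx = np.fromiter((index[i] for i in anchored), dtype=np.int64, count=len(anchored))
    a = np.array([act.values[i] for i in anchored])
    b = np.zeros(len(node_ids))
    b[anchored_idx] = cfg.anchor_weight * a

    rng = substream(cfg.seed, "k")
    null = np.empty(cfg.permutations)
    accepted_loops = 0
    for p in range(cfg.permutations):
        for attempt in range(10):
            perm_tgt = tgt[rng.permutation(len(tgt))]
            if not np.any(perm_tgt == src):
                break
        else:
            accepted_loops += 1
        matrix = _build_matrix(len(node_ids), src, perm_tgt, sign, weight, anchored_idx,
                               cfg.anchor_weight, cfg.ridge)
        c = spsolve(matrix, b)
        null[p] = float(np.mean(c**2))
    if accepted_loops:
        logger.info("accepted %d permutations containing self-loops after 10 redraw attempts", accepted_loops)
    return _pvalue(null, observed, cfg.permutations), null


# ---------------------------------------------------------------------------
# full score and fold change
# ---------------------------------------------------------------------------


def score(
    model: TwoLayerModel,
    profile: ExpressionProfile,
    cfg: FitConfig | None = None,
    with_ci: bool = True,
    with_o: bool = True,
    with_k: bool = True,
    keep_null: bool = False,
) -> ScoreResult:
    """Run the full pipeline: activities, fit, NPA, CI and o/k statistics."""
    cfg = cfg or FitConfig()
    act = infer_activities(model, profile)
    coeff = fit_coefficients(model, act, cfg)
    npa = compute_npa(coeff)
    contrib = node_contributions(coeff)
    ci = confidence_interval(model, profile, cfg) if with_ci else (npa, npa)
    p_o, o_null = o_statistic(model, profile, cfg) if with_o else (float("nan"), None)
    p_k, k_null = k_statistic(model, profile, cfg) if with_k else (float("nan"), None)
    return ScoreResult(
        npa=npa,
        ci=ci,
        p_o=p_o,
        p_k=p_k,
        coefficients=coeff,
        contributions=contrib,
        config=cfg,
        activities=act,
        o_null=o_null if keep_null else None,
        k_null=k_null if keep_null else None,
    )


def npa_fold_change(treatment: ScoreResult, control: ScoreResult) -> tuple[float, tuple[float, float]]:
    """Treatment NPA as fold change over a control, with proportionally scaled CI."""
    if control.npa <= 0:
        raise ScoringError("control unperturbed (NPA = 0); fold change undefined")
    fold = treatment.npa / control.npa
    scaled_ci = (treatment.ci[0] / control.npa, treatment.ci[1] / control.npa)
    return fold, scaled_ci


def consistency_functional(
    model: TwoLayerModel, act: ActivityMap, coeff: Mapping[str, float], lam: float = 1.0
) -> float:
    """Evaluate J(c) directly; used for diagnostics and as an optimisation target."""
    values = coeff.values if isinstance(coeff, CoefficientMap) else coeff
    j = 0.0
    for e in model.network.scoring_edges():
        j += e.weight * (values[e.target] - e.sign * values[e.source]) ** 2
    for inode, a in act.values.items():
        j += lam * (values[inode] - a) ** 2
    return j
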