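"""Distance-matrix PERMANOVA with restricted permutations, and disparity tests.

The repeated-measures design (every subject imaged at stages T0/T1/T2) makes
observations within a subject correlated, so significance is assessed by
restricted permutation: stage labels (and the stage:group interaction) are
shuffled only within each participant, while the between-subject treatment
factor is tested by permuting group labels across whole subjects — a
within-subject shuffle cannot move a between-subject factor. Sums of squares
are partitioned sequentially (Type I, order stage, group, stage:group) from
the Gower-centered squared-distance matrix via projection matrices; because
the distances used here are Euclidean distances between superimposed shape
coordinates, this partition coincides exactly with the coordinate-space
linear-model decomposition (a property the test suite checks).

Empirical p-values follow the "larger or equal" rule: with sampled
permutations p = (#{F* >= F_obs} + 1) / (B + 1), counting the identity; when
the restricted permutation group is small (<= 1024 elements by default) it is
enumerated exhaustively and p = #{F* >= F_obs} / N is exact.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import DesignTable

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationScheme",
    "pairwise_distance_matrix",
    "gower_center",
    "permanova",
    "partial_r2",
    "pairwise_posthoc",
    "per_landmark_analysis",
    "procrustes_variance",
    "disparity_test",
    "run_form_analysis",
]

DEFAULT_TERMS = ("stage", "group", "stage:group")


@dataclass
class PermutationScheme:
    """Restricted-permutation plan for the repeated-measures design.

    ``subjects`` gives the block (participant) of each observation.
    ``rules`` maps model terms to "within_subject" (labels shuffled inside
    each participant) or "between_subject" (whole-subject group relabeling).
    Setting every rule to "within_subject" reproduces the single-rule,
    within-participant-only scheme.
    """

    subjects: np.ndarray
    n_perms: int = 10_000
    seed: int = 0
    rules: dict = field(
        default_factory=lambda: {
            "stage": "within_subject",
            "group": "between_subject",
            "stage:group": "within_subject",
        }
    )
    enumerate_threshold: int = 1024

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)
        if self.n_perms < 1:
            raise ValueError("n_perms must be >= 1")

    def blocks(self) -> list[np.ndarray]:
        """Observation indices per subject, in order of first appearance."""
        order = pd.unique(self.subjects)
        return [np.flatnonzero(self.subjects == s) for s in order]


# ---------------------------------------------------------------------------
# Distance matrices and SS decomposition


def pairwise_distance_matrix(shapes: np.ndarray) -> np.ndarray:
    """n x n symmetric matrix of Euclidean (Procrustes) distances between
    flattened shape coordinate matrices."""
    flat = np.asarray(shapes, dtype=float).reshape(len(shapes), -1)
    return squareform(pdist(flat))


def gower_center(dist: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -0.5 * J D^2 J."""
    dist = np.asarray(dist, dtype=float)
    n = len(dist)
    a = -0.5 * dist**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Full-rank treatment coding (drop first level, levels in appearance order)."""
    levels = list(pd.unique(labels))
    return np.column_stack(
        [(labels == lev).astype(float) for lev in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(labels), 0))


def _term_columns(term: str, stage: np.ndarray, group: np.ndarray) -> np.ndarray:
    if term == "stage":
        return _dummies(stage)
    if term == "group":
        return _dummies(group)
    if term == "stage:group":
        s = _dummies(stage)
        g = _dummies(group)
        if s.size == 0 or g.size == 0:
            return np.empty((len(stage), 0))
        return np.einsum("ni,nj->nij", s, g).reshape(len(stage), -1)
    raise ValueError(f"unknown model term {term!r}")


def _projector(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(x) and its rank (SVD-based, tolerant of
    rank deficiency)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int((s > tol).sum())
    uq = u[:, :r]
    return uq @ uq.T, r


def _sequential_hats(
    stage: np.ndarray, group: np.ndarray, terms
) -> tuple[list[np.ndarray], list[int], np.ndarray]:
    """Sequential (Type I) projector increments per term, their df, and the
    full-model projector (including intercept)."""
    n = len(stage)
    x = np.ones((n, 1))
    h_prev, r_prev = _projector(x)
    hats, dfs = [], []
    for term in terms:
        x = np.hstack([x, _term_columns(term, stage, group)])
        h, r = _projector(x)
        hats.append(h - h_prev)
        dfs.append(r - r_prev)
        h_prev, r_prev = h, r
    return hats, dfs, h_prev


def _trace_hg(h: np.ndarray, g: np.ndarray) -> float:
    return float(np.sum(h * g))  # tr(HG) for symmetric G


# ---------------------------------------------------------------------------
# Permutation generation


def _within_subject_perms(scheme: PermutationScheme, rng: np.random.Generator):
    """Yield ('exact', perms) or ('sampled', perms) observation permutations
    that shuffle only within subject blocks."""
    blocks = scheme.blocks()
    singletons = sum(1 for b in blocks if len(b) == 1)
    if singletons:
        logger.info("%d subject(s) with a single observation: no shuffling there",
                    singletons)
    group_size = 1.0
    for b in blocks:
        group_size *= math.factorial(len(b))
        if group_size > scheme.enumerate_threshold:
            break
    n = len(scheme.subjects)
    if group_size <= scheme.enumerate_threshold:
        perms = []
        per_block = [list(itertools.permutations(b)) for b in blocks]
        for combo in itertools.product(*per_block):
            p = np.empty(n, dtype=int)
            for b, choice in zip(blocks, combo):
                p[b] = choice
            perms.append(p)
        return "exact", perms
    perms = []
    for _ in range(scheme.n_perms):
        p = np.arange(n)
        for b in blocks:
            p[b] = rng.permutation(p[b])
        perms.append(p)
    return "sampled", perms


def _between_subject_perms(scheme: PermutationScheme, rng: np.random.Generator):
    """Whole-subject permutations: subject s takes the observations slots of
    subject perm[s]. Returned as observation-level index permutations; valid
    when subjects share the same within-block layout (balanced design)."""
    blocks = scheme.blocks()
    sizes = {len(b) for b in blocks}
    s = len(blocks)
    n = len(scheme.subjects)
    if len(sizes) != 1:
        # unbalanced: fall back to within-subject-only scheme for this term
        warnings.warn(
            "between-subject permutation requires a balanced design; "
            "term tested with within-subject shuffles instead",
            RuntimeWarning,
        )
        return _within_subject_perms(scheme, rng)
    if math.factorial(s) <= scheme.enumerate_threshold:
        perms = []
        for combo in itertools.permutations(range(s)):
            p = np.empty(n, dtype=int)
            for b, j in zip(blocks, combo):
                p[b] = blocks[j]
            perms.append(p)
        return "exact", perms
    perms = []
    for _ in range(scheme.n_perms):
        combo = rng.permutation(s)
        p = np.empty(n, dtype=int)
        for b, j in zip(blocks, combo):
            p[b] = blocks[j]
        perms.append(p)
    return "sampled", perms


def _perms_for_rule(rule: str, scheme: PermutationScheme, rng: np.random.Generator):
    if rule == "within_subject":
        return _within_subject_perms(scheme, rng)
    if rule == "between_subject":
        return _between_subject_perms(scheme, rng)
    raise ValueError(f"unknown permutation rule {rule!r}")


def _perm_pvalue(f_obs: float, f_perm: np.ndarray, mode: str) -> float:
    hits = int(np.sum(f_perm >= f_obs - 1e-12))
    if mode == "exact":
        return hits / len(f_perm)
    return (hits + 1) / (len(f_perm) + 1)


# ---------------------------------------------------------------------------
# PERMANOVA


def partial_r2(ss_term: float, ss_residual: float) -> float:
    """Coefficient of partial determination: SS_term / (SS_term + SS_residual)."""
    denom = ss_term + ss_residual
    if denom == 0:
        raise ValueError("partial R2 undefined: SS_term + SS_residual = 0")
    return ss_term / denom


def permanova(
    dist: np.ndarray,
    design: DesignTable,
    scheme: PermutationScheme,
    terms=DEFAULT_TERMS,
) -> pd.DataFrame:
    """Permutational MANOVA of a distance matrix under the study design.

    Returns a table with one row per term plus Residual and Total, holding
    df, SS, pseudo-F, partial R² and the restricted-permutation p-value.
    Terms are fitted sequentially in the given order.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(dist)
    stage = design.stage_labels
    group = design.groups
    if len(stage) != n:
        raise ValueError("design length does not match distance matrix")
    g = gower_center(dist)
    ss_total = float(np.trace(g))
    if ss_total <= 1e-12:
        raise ValueError("total sum of squares is zero: constant response")

    hats, dfs, h_full = _sequential_hats(stage, group, terms)
    ss_terms = [_trace_hg(h, g) for h in hats]
    n_eff = n
    df_res = n_eff - 1 - sum(dfs)
    ss_res = ss_total - sum(ss_terms)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    f_obs = [
        (ss / df) / (ss_res / df_res) if df > 0 else np.nan
        for ss, df in zip(ss_terms, dfs)
    ]

    rng = np.random.default_rng(scheme.seed)
    pvals = []
    for t_idx, term in enumerate(terms):
        if dfs[t_idx] == 0:
            pvals.append(np.nan)
            continue
        rule = scheme.rules.get(term, "within_subject")
        mode, perms = _perms_for_rule(rule, scheme, rng)
        h_t = hats[t_idx]
        df_t = dfs[t_idx]
        f_perm = np.empty(len(perms))
        for i, p in enumerate(perms):
            gp = g[np.ix_(p, p)]
            ss_t = _trace_hg(h_t, gp)
            ss_r = float(np.trace(gp)) - sum(_trace_hg(h, gp) for h in hats)
            f_perm[i] = (ss_t / df_t) / (ss_r / df_res)
        pvals.append(_perm_pvalue(f_obs[t_idx], f_perm, mode))

    rows = {}
    for term, df_t, ss_t, f_t, p_t in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows[term] = {
            "df": df_t,
            "SS": ss_t,
            "F": f_t,
            "partial_R2": partial_r2(ss_t, ss_res) if df_t > 0 else np.nan,
            "p": p_t,
        }
    rows["Residual"] = {"df": df_res, "SS": ss_res, "F": np.nan,
                        "partial_R2": np.nan, "p": np.nan}
    rows["Total"] = {"df": n_eff - 1, "SS": ss_total, "F": np.nan,
                     "partial_R2": np.nan, "p": np.nan}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Post-hoc pairwise stage comparisons


def pairwise_posthoc(
    shapes: np.ndarray,
    design: DesignTable,
    scheme: PermutationScheme,
    terms=DEFAULT_TERMS,
) -> pd.DataFrame:
    """Pairwise stage comparisons: Procrustes distance between stage mean
    shapes, stage-term partial R² and within-subject permutation p, computed
    on the subset of subjects observed at both stages."""
    shapes = np.asarray(shapes, dtype=float)
    stage = design.stage_labels
    stages_present = [s for s in design.stages if (stage == s).sum() > 0]
    skipped = set(design.stages) - set(stages_present)
    if skipped:
        warnings.warn(f"stages with no observations skipped: {sorted(skipped)}",
                      RuntimeWarning)
    out = []
    for a, b in itertools.combinations(stages_present, 2):
        in_pair = np.isin(stage, [a, b])
        subj = design.subjects[in_pair]
        st = stage[in_pair]
        both = {s for s in subj if {a, b} <= set(st[subj == s])}
        keep = in_pair & np.isin(design.subjects, list(both))
        if keep.sum() < 4:
            warnings.warn(f"pair {a}-{b}: too few paired subjects; skipped",
                          RuntimeWarning)
            continue
        sub_shapes = shapes[keep]
        sub_design = DesignTable(
            design.table.loc[keep].reset_index(drop=True), stages=design.stages
        )
        sub_scheme = PermutationScheme(
            subjects=sub_design.subjects,
            n_perms=scheme.n_perms,
            seed=scheme.seed,
            rules=scheme.rules,
            enumerate_threshold=scheme.enumerate_threshold,
        )
        sub_terms = [t for t in terms
                     if _term_columns(t, sub_design.stage_labels,
                                      sub_design.groups).size > 0]
        table = permanova(
            pairwise_distance_matrix(sub_shapes), sub_design, sub_scheme,
            terms=tuple(sub_terms),
        )
        mean_a = sub_shapes[sub_design.stage_labels == a].mean(axis=0)
        mean_b = sub_shapes[sub_design.stage_labels == b].mean(axis=0)
        pd_ab = float(np.sqrt(((mean_a - mean_b) ** 2).sum()))
        out.append({
            "pair": f"{a}-{b}",
            "PD": pd_ab,
            "partial_R2": table.loc["stage", "partial_R2"],
            "p": table.loc["stage", "p"],
        })
    return pd.DataFrame(out).set_index("pair")


# ---------------------------------------------------------------------------
# Per-landmark localization


def per_landmark_analysis(
    shapes: np.ndarray,
    design: DesignTable,
    scheme: PermutationScheme,
    mm_scale: float,
    terms=DEFAULT_TERMS,
    n_perms: int | None = None,
) -> dict:
    """Localize stage effects landmark by landmark.

    The whole-face PERMANOVA model is re-fitted per quasi-landmark with that
    landmark's 3 coordinates as the response (same sequential terms, same
    within-subject permutation rule for the stage term). Shape-unit
    displacements are converted to mm by ``mm_scale`` (conventionally the
    grand mean centroid size of the dataset).

    Returns a dict with ``stats`` (per-landmark R², raw and BH-adjusted p of
    the stage term), ``displacements`` {stage-pair: (k, 3) mm vectors},
    ``magnitudes`` {stage-pair: (k,) mm}, and ``summary`` (mean/SD/median of
    magnitudes per pair). Set ``n_perms=0`` to skip the permutation p-values
    (magnitudes and R² only).
    """
    shapes = np.asarray(shapes, dtype=float)
    n, k, _ = shapes.shape
    stage = design.stage_labels
    group = design.groups
    if n_perms is None:
        n_perms = scheme.n_perms

    hats, dfs, h_full = _sequential_hats(stage, group, terms)
    t_stage = list(terms).index("stage")
    df_stage = dfs[t_stage]
    df_res = n - 1 - sum(dfs)
    h0 = np.full((n, n), 1.0 / n)
    resid_proj = np.eye(n) - h_full

    y = shapes.reshape(n, 3 * k)

    def _per_landmark_ss(yy: np.ndarray, h: np.ndarray) -> np.ndarray:
        proj = h @ yy
        return (proj**2).reshape(n, k, 3).sum(axis=(0, 2))

    ss_stage = _per_landmark_ss(y, hats[t_stage])
    ss_res = _per_landmark_ss(y, resid_proj)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_stage / df_stage) / (ss_res / df_res)
        r2 = ss_stage / (ss_stage + ss_res)

    p_raw = np.full(k, np.nan)
    if n_perms > 0:
        sub_scheme = PermutationScheme(
            subjects=scheme.subjects, n_perms=n_perms, seed=scheme.seed,
            rules=scheme.rules, enumerate_threshold=scheme.enumerate_threshold,
        )
        rng = np.random.default_rng(sub_scheme.seed)
        mode, perms = _perms_for_rule(
            scheme.rules.get("stage", "within_subject"), sub_scheme, rng
        )
        hits = np.zeros(k)
        for p in perms:
            yp = y[p]
            ss_s = _per_landmark_ss(yp, hats[t_stage])
            ss_r = _per_landmark_ss(yp, resid_proj)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_p = (ss_s / df_stage) / (ss_r / df_res)
            hits += f_p >= f_obs - 1e-12
        if mode == "exact":
            p_raw = hits / len(perms)
        else:
            p_raw = (hits + 1) / (len(perms) + 1)

    ok = np.isfinite(p_raw)
    p_adj = np.full(k, np.nan)
    if ok.any():
        p_adj[ok] = multipletests(p_raw[ok], method="fdr_bh")[1]

    stats = pd.DataFrame({
        "R2_stage": r2, "p_stage": p_raw, "p_stage_bh": p_adj,
    })

    displacements: dict[str, np.ndarray] = {}
    magnitudes: dict[str, np.ndarray] = {}
    summary_rows = []
    stages_present = [s for s in design.stages if (stage == s).sum() > 0]
    for a, b in itertools.combinations(stages_present, 2):
        mean_a = shapes[stage == a].mean(axis=0)
        mean_b = shapes[stage == b].mean(axis=0)
        disp = (mean_b - mean_a) * mm_scale
        mag = np.linalg.norm(disp, axis=1)
        key = f"{a}-{b}"
        displacements[key] = disp
        magnitudes[key] = mag
        summary_rows.append({
            "pair": key,
            "mean_mm": float(mag.mean()),
            "sd_mm": float(mag.std(ddof=1)),
            "median_mm": float(np.median(mag)),
        })
    summary = pd.DataFrame(summary_rows).set_index("pair")
    return {"stats": stats, "displacements": displacements,
            "magnitudes": magnitudes, "summary": summary}


# ---------------------------------------------------------------------------
# Procrustes variance (morphological disparity)


def procrustes_variance(shapes: np.ndarray, groups: np.ndarray) -> pd.Series:
    """Per-group Procrustes variance: mean squared (Procrustes) distance of
    group members from the group mean shape, PV_g = (1/n_g) Σ ||x_i − x̄_g||²."""
    shapes = np.asarray(shapes, dtype=float).reshape(len(shapes), -1)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        sel = shapes[groups == g]
        if len(sel) == 0:
            raise ValueError(f"empty group {g!r}")
        resid = sel - sel.mean(axis=0)
        out[g] = float((resid**2).sum() / len(sel))
    return pd.Series(out, name="procrustes_variance")


def disparity_test(
    shapes: np.ndarray,
    groups: np.ndarray,
    n_perms: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise comparison of Procrustes variances between groups.

    Group-mean-centered residual vectors are pooled and permuted among
    groups; for each pair the statistic is |ΔPV| and
    p = (#{|ΔPV*| >= |ΔPV|} + 1) / (B + 1). The signed ΔVar column follows
    the a−b convention of the pair label.
    """
    flat = np.asarray(shapes, dtype=float).reshape(len(shapes), -1)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    pv = procrustes_variance(flat, groups)
    sizes = {g: int((groups == g).sum()) for g in levels}
    singles = [g for g in levels if sizes[g] < 2]
    if singles:
        warnings.warn(f"groups of size 1, test skipped for: {singles}",
                      RuntimeWarning)

    # squared residual norms are sufficient statistics for PV under permutation
    sqnorm = np.empty(len(flat))
    for g in levels:
        sel = groups == g
        resid = flat[sel] - flat[sel].mean(axis=0)
        sqnorm[sel] = (resid**2).sum(axis=1)

    rng = np.random.default_rng(seed)
    group_codes = {g: i for i, g in enumerate(levels)}
    codes = np.array([group_codes[g] for g in groups])
    perm_pv = np.empty((n_perms, len(levels)))
    for b in range(n_perms):
        perm = rng.permutation(len(flat))
        sq = sqnorm[perm]
        for i, g in enumerate(levels):
            perm_pv[b, i] = sq[codes == group_codes[g]].mean()

    rows = []
    for a, b in itertools.combinations(levels, 2):
        delta = pv[a] - pv[b]
        if sizes[a] < 2 or sizes[b] < 2:
            p = np.nan
        else:
            d_star = np.abs(perm_pv[:, group_codes[a]] - perm_pv[:, group_codes[b]])
            p = (int(np.sum(d_star >= abs(delta) - 1e-15)) + 1) / (n_perms + 1)
        rows.append({
            "pair": f"{a}-{b}", "PV_a": pv[a], "PV_b": pv[b],
            "delta_var": delta, "p": p,
        })
    return pd.DataFrame(rows).set_index("pair")


# ---------------------------------------------------------------------------
# Form-space analysis


def run_form_analysis(
    forms: np.ndarray,
    design: DesignTable,
    scheme: PermutationScheme,
    n_perms_disparity: int | None = None,
) -> dict:
    """Apply the shape machinery in form space (coordinates in mm).

    Returns {"permanova": table, "pairwise": table, "disparity": table};
    distances and variances carry mm units.
    """
    forms = np.asarray(forms, dtype=float)
    dist = pairwise_distance_matrix(forms)
    table = permanova(dist, design, scheme)
    pairwise = pairwise_posthoc(forms, design, scheme)
    labels = np.array([
        f"{g}:{s}" for g, s in zip(design.groups, design.stage_labels)
    ])
    disp = disparity_test(
        forms, labels,
        n_perms=n_perms_disparity if n_perms_disparity is not None else scheme.n_perms,
        seed=scheme.seed,
    )
    return {"permanova": table, "pairwise": pairwise, "disparity": disp}
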