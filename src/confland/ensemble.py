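"""Microstate coverage accounting and mutant differential contact analysis.

Coverage operations quantify how many of the model's microstates are explored
by given subsets of trajectories (per seed structure, per trajectory budget),
supporting Venn-style set algebra, trajectory-number x trajectory-length
coverage grids, and minimal-simulation-time queries.  Contact operations
subtract a wild-type mean contact map from a mutant map, select contacts by
the joint absolute/relative-change thresholds, extract candidate
neo-conformation frames, expand candidate clusters by RMSD, and compare
new-microstate discovery rates between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._types import DiscreteTrajectorySet
from .featurize import ContactMap, FeaturizationConfig, pairwise_min_distances
from .landscape import SuperpositionConfig, superpose_rmsd

__all__ = [
    "CoverageResult",
    "DiffContactMap",
    "visited_states",
    "coverage_by_sets",
    "venn_regions",
    "coverage_contour",
    "minimal_time_to_coverage",
    "differential_contact_map",
    "extract_candidate_frames",
    "expand_cluster_by_rmsd",
    "discovery_curve",
]


@dataclass
class CoverageResult:
    """States covered by a set expression over labeled trajectory sets."""

    set_expression: str
    covered_states: frozenset
    n_total: int

    def __post_init__(self) -> None:
        self.covered_states = frozenset(int(s) for s in self.covered_states)
        if self.covered_states and (
            min(self.covered_states) < 0 or max(self.covered_states) >= self.n_total
        ):
            raise ValueError("covered states out of range")

    @property
    def n_covered(self) -> int:
        return len(self.covered_states)


@dataclass
class DiffContactMap:
    """Mutant-minus-wild-type contact-change maps and the selected pairs.

    ``absolute`` is mutant mean minus WT mean (in [-1, 1]); ``relative`` is
    |absolute| / WT, forced to 0 where WT is 0; ``selected_pairs`` are the
    pairs passing both thresholds (strict inequalities).  For a residue
    deletion, all changes touching that position are zeroed.
    """

    absolute: np.ndarray
    relative: np.ndarray
    selected_pairs: list
    abs_thresh: float
    rel_thresh: float
    deletion_residue: int | None = None


def visited_states(dtrajs) -> frozenset:
    """Set of states visited anywhere in a collection of dtrajs."""
    if isinstance(dtrajs, DiscreteTrajectorySet):
        dtrajs = dtrajs.dtrajs
    out: set = set()
    for d in dtrajs:
        out.update(np.unique(d).tolist())
    return frozenset(int(s) for s in out)


def _eval_expression(expr: str, sets: dict) -> frozenset:
    """Evaluate a set expression with labels and the operators | & - ( )."""
    import re

    tokens = re.findall(r"[A-Za-z_][A-Za-z0-9_\-]*|[|&()−-]|[∪∩]", expr)
    pos = 0

    def parse_atom():
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"unexpected end of expression: {expr!r}")
        tok = tokens[pos]
        if tok == "(":
            pos += 1
            val = parse_union()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError("unbalanced parentheses")
            pos += 1
            return val
        pos += 1
        if tok not in sets:
            raise KeyError(f"unknown set label {tok!r}")
        return sets[tok]

    def parse_inter():
        nonlocal pos
        val = parse_atom()
        while pos < len(tokens) and tokens[pos] in ("&", "∩"):
            pos += 1
            val = val & parse_atom()
        return val

    def parse_union():
        nonlocal pos
        val = parse_inter()
        while pos < len(tokens) and tokens[pos] in ("|", "∪", "-", "−", "−"):
            op = tokens[pos]
            pos += 1
            rhs = parse_inter()
            val = val | rhs if op in ("|", "∪") else val - rhs
        return val

    result = parse_union()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in expression {expr!r}")
    return frozenset(result)


def coverage_by_sets(dtraj_sets: dict, expression: str, n_total: int | None = None) -> CoverageResult:
    """Evaluate a union/intersection/difference expression over labeled sets.

    ``dtraj_sets`` maps labels to DiscreteTrajectorySets (or dtraj lists);
    ``expression`` uses the labels with ``|``/``∪`` (union), ``&``/``∩``
    (intersection) and ``-`` (difference), e.g. ``"(A | B) & C - D"``.
    """
    state_sets = {lab: visited_states(v) for lab, v in dtraj_sets.items()}
    if n_total is None:
        n_candidates = [
            v.n_states for v in dtraj_sets.values() if isinstance(v, DiscreteTrajectorySet)
        ]
        if n_candidates and len(set(n_candidates)) > 1:
            raise ValueError("inconsistent n_states across sets")
        n_total = n_candidates[0] if n_candidates else (max(map(max, state_sets.values())) + 1)
    covered = _eval_expression(expression, state_sets)
    return CoverageResult(set_expression=expression, covered_states=covered, n_total=n_total)


def venn_regions(dtraj_sets: dict, n_total: int | None = None) -> dict:
    """Exclusive Venn region counts for every nonempty label combination.

    The region keyed by a label tuple contains states visited by *all* those
    sets and by *no* other set.
    """
    state_sets = {lab: visited_states(v) for lab, v in dtraj_sets.items()}
    labels = list(state_sets)
    out = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            region = frozenset.intersection(*(state_sets[c] for c in combo))
            for other in labels:
                if other not in combo:
                    region = region - state_sets[other]
            out[combo] = len(region)
    return out


def coverage_contour(
    dtrajs: DiscreteTrajectorySet,
    traj_step: int = 50,
    length_step: int = 50,
    n_draws: int = 5,
    seed: int = 0,
):
    """Mean microstate coverage on an (n_trajectories, max_length) grid.

    For each grid point, ``n_draws`` random draws of trajectories without
    replacement are truncated to the maximum length and the distinct states
    counted; draws are averaged.  Lengths are in frames.  Returns
    ``(n_traj_axis, length_axis, grid)`` with grid shape
    (len(n_traj_axis), len(length_axis)).
    """
    trajs = dtrajs.dtrajs
    n_pool = len(trajs)
    if n_pool == 0:
        raise ValueError("empty trajectory pool")
    n_states = dtrajs.n_states
    max_len = max(len(d) for d in trajs)

    # first-visit frame of each state per trajectory (inf when never visited)
    first = np.full((n_pool, n_states), np.inf)
    for i, d in enumerate(trajs):
        states, idx = np.unique(d, return_index=True)
        first[i, states] = idx

    def axis(maximum, step):
        ax = list(range(0, maximum + 1, step))
        if ax[-1] != maximum:
            ax.append(maximum)
        return np.array(ax)

    n_traj_axis = axis(n_pool, traj_step)
    length_axis = axis(max_len, length_step)

    rng = np.random.default_rng(seed)
    grid = np.zeros((len(n_traj_axis), len(length_axis)))
    for _ in range(n_draws):
        perm = rng.permutation(n_pool)
        for a, n_traj in enumerate(n_traj_axis):
            if n_traj == 0:
                continue
            chosen = perm[:n_traj]
            min_first = first[chosen].min(axis=0)
            min_first_sorted = np.sort(min_first[np.isfinite(min_first)])
            # coverage at max length L = #states first visited before frame L
            grid[a] += np.searchsorted(min_first_sorted, length_axis, side="left")
    grid /= n_draws
    return n_traj_axis, length_axis, grid


def minimal_time_to_coverage(
    n_traj_axis, length_axis, grid, fraction: float, n_total: int, frame_time: float = 1.0
) -> float:
    """Minimum aggregate simulation time reaching a target coverage fraction.

    Aggregate time of a grid point is n_traj * max_length * frame_time.
    Raises if the target coverage is never attained on the grid.
    """
    target = fraction * n_total
    ok = np.asarray(grid) >= target
    if not ok.any():
        raise ValueError(
            f"coverage target {fraction:.0%} of {n_total} states not attained on the grid"
        )
    budget = np.outer(np.asarray(n_traj_axis, float), np.asarray(length_axis, float)) * frame_time
    return float(budget[ok].min())


def differential_contact_map(
    mutant: ContactMap,
    wildtype: ContactMap,
    abs_thresh: float = 0.2,
    rel_thresh: float = 3.0,
    deletion: int | None = None,
) -> DiffContactMap:
    """Differential contact map with joint absolute/relative selection.

    The absolute change is mutant minus wild-type mean contact fraction; the
    relative change is |absolute| / wild-type (0 where the wild-type fraction
    is 0, avoiding spurious infinite enrichment of never-formed contacts).
    Contacts with absolute change > ``abs_thresh`` AND relative change >
    ``rel_thresh`` (strict) are selected.  With ``deletion`` set, every
    change touching that residue position is zeroed first.
    """
    A, W = mutant.matrix, wildtype.matrix
    if A.shape != W.shape:
        raise ValueError("contact maps have mismatched shapes")
    absolute = A - W
    if deletion is not None:
        absolute = absolute.copy()
        absolute[deletion, :] = 0.0
        absolute[:, deletion] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.where(W > 0, np.abs(absolute) / np.where(W > 0, W, 1.0), 0.0)
    n = A.shape[0]
    selected = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if abs(absolute[i, j]) > abs_thresh and relative[i, j] > rel_thresh
    ]
    return DiffContactMap(
        absolute=absolute,
        relative=relative,
        selected_pairs=selected,
        abs_thresh=abs_thresh,
        rel_thresh=rel_thresh,
        deletion_residue=deletion,
    )


def top_changed_contacts(diff: DiffContactMap, n_top: int = 5, abs_floor: float = 0.2):
    """Up to ``n_top`` most positive and most negative contact changes.

    Only contacts whose absolute change exceeds ``abs_floor`` in magnitude
    qualify.  Returns (positive_pairs, negative_pairs).
    """
    A = diff.absolute
    n = A.shape[0]
    cands = [(i, j, A[i, j]) for i in range(n) for j in range(i + 1, n) if abs(A[i, j]) > abs_floor]
    pos = sorted([c for c in cands if c[2] > 0], key=lambda c: -c[2])[:n_top]
    neg = sorted([c for c in cands if c[2] < 0], key=lambda c: c[2])[:n_top]
    return [(i, j) for i, j, _ in pos], [(i, j) for i, j, _ in neg]


def extract_candidate_frames(
    trajs,
    diff: DiffContactMap,
    burn_in: int = 0,
    n_top: int = 5,
    stride: int = 10,
    stride_cap: int = 7500,
    stride_wide: int = 20,
    config: FeaturizationConfig | None = None,
) -> list:
    """Candidate neo-conformation frames from contact-change signatures.

    After discarding ``burn_in`` frames of each trajectory, a frame
    qualifies when all of the top-positive contacts are formed OR none of
    the top-negative contacts is formed.  Qualifying frames are strided by
    ``stride`` per trajectory, widening to ``stride_wide`` when a trajectory
    has more than ``stride_cap`` qualifying frames.  Returns
    ``(trajectory_index, frame_index)`` pairs; an empty list when nothing
    qualifies.
    """
    config = config or FeaturizationConfig()
    pos_pairs, neg_pairs = top_changed_contacts(diff, n_top=n_top, abs_floor=diff.abs_thresh)
    if not pos_pairs and not neg_pairs:
        return []
    out = []
    for ti, traj in enumerate(trajs):
        ft = pairwise_min_distances(traj, config)
        pair_col = {p: c for c, p in enumerate(ft.column_labels)}
        contact = ft.features < config.contact_map_cutoff
        n_frames = contact.shape[0]
        qual = np.zeros(n_frames, dtype=bool)
        if pos_pairs:
            cols = [pair_col[p] for p in pos_pairs]
            qual |= contact[:, cols].all(axis=1)
        if neg_pairs:
            cols = [pair_col[p] for p in neg_pairs]
            qual |= ~contact[:, cols].any(axis=1)
        qual[:burn_in] = False
        idx = np.nonzero(qual)[0]
        step = stride_wide if len(idx) > stride_cap else stride
        out.extend((ti, int(f)) for f in idx[::step])
    return out


def expand_cluster_by_rmsd(
    cluster_frames,
    all_frames,
    threshold: float = 0.3,
    stride: int = 10,
    config: SuperpositionConfig | None = None,
    residue_ids=None,
) -> list:
    """Frames structurally similar to a candidate cluster.

    Every ``stride``-th frame of ``all_frames`` whose minimum superposed
    RMSD to any cluster frame is below ``threshold`` (nm) is returned as a
    frame index into ``all_frames``.
    """
    cluster = np.asarray(cluster_frames, dtype=float)
    if cluster.ndim == 2:
        cluster = cluster[None]
    if cluster.shape[0] == 0:
        raise ValueError("empty cluster")
    frames = np.asarray(all_frames, dtype=float)
    picked = []
    for k in range(0, frames.shape[0], stride):
        rmsds = superpose_rmsd(cluster, frames[k], config=config, residue_ids=residue_ids)
        if np.min(rmsds) < threshold:
            picked.append(k)
    return picked


def discovery_curve(
    joint_dtrajs: DiscreteTrajectorySet,
    query_groups,
    reference_groups,
) -> np.ndarray:
    """Cumulative new-microstate discoveries by a query cohort.

    Both cohorts share one joint discretization; ``group_ids`` identify the
    cohorts.  States ever visited by the reference cohort are excluded; the
    curve counts, as a function of aggregate query frames (trajectories
    concatenated in their given order), how many never-before-seen states
    the query cohort has discovered.
    """
    qset = set(np.atleast_1d(query_groups).tolist())
    rset = set(np.atleast_1d(reference_groups).tolist())
    ref_trajs = [
        d for d, g in zip(joint_dtrajs.dtrajs, joint_dtrajs.group_ids) if g in rset
    ]
    qry_trajs = [
        d for d, g in zip(joint_dtrajs.dtrajs, joint_dtrajs.group_ids) if g in qset
    ]
    ref_seen = visited_states(ref_trajs) if ref_trajs else frozenset()
    stream = np.concatenate(qry_trajs) if qry_trajs else np.array([], dtype=np.int64)
    novel = np.array([s not in ref_seen for s in stream])
    first_mask = np.zeros(len(stream), dtype=bool)
    seen: set = set()
    for t, (s, isnew) in enumerate(zip(stream, novel)):
        if isnew and s not in seen:
            first_mask[t] = True
            seen.add(int(s))
    return np.cumsum(first_mask)
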