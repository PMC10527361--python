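"""Upstream kinase ranking from peptide-level group differences.

Phosphorylation changes on the array are attributed to kinases through a
kinase -> substrate-peptide mapping with per-pair confidence ranks. For a
kinase's substrate set the *kinase statistic* is the mean standardized
group difference (size and direction of the activity change). Two
permutation scores qualify it:

* significance score, -log10 of the p-value under permutation of the
  sample labels (is the change larger than chance?);
* specificity score, -log10 of the p-value under random substrate sets of
  the same size drawn from the filtered peptides (is the change confined
  to this kinase's substrates, or would any peptide set show it?).

Both are averaged over a ladder of substrate-set sizes (top-k peptides by
mapping rank); their sum is the kinase score, which orders the final list.
A matrix-wide shift therefore earns high significance but near-zero
specificity, while a substrate-confined shift earns both.

Mapping hygiene: array peptides whose sequence matches more than one human
protein ambiguously are vetted with PAM30 — a mapping survives only when
the best ungapped-window PAM30 score against the target protein equals the
peptide's self-score (similarity ratio exactly 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

DEFAULT_B = 500
DEFAULT_LADDER = (4, 6, 8, 10, 12)
DEFAULT_MIN_SUBSTRATES = 3
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_PAM30 = None
_PAM30_LOOKUP = None


def pam30_matrix() -> np.ndarray:
    """The 20x20 PAM30 substitution matrix over the canonical residues."""
    global _PAM30
    if _PAM30 is None:
        raw = substitution_matrices.load("PAM30")
        m = np.zeros((20, 20), dtype=int)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                m[i, j] = int(raw[a, b])
        _PAM30 = m
    return _PAM30


def _encode(seq: str) -> np.ndarray:
    global _PAM30_LOOKUP
    if _PAM30_LOOKUP is None:
        _PAM30_LOOKUP = {a: i for i, a in enumerate(AMINO_ACIDS)}
    try:
        return np.array([_PAM30_LOOKUP[c] for c in seq.upper()], dtype=int)
    except KeyError as e:
        raise InvalidArgumentError(f"invalid amino-acid residue {e.args[0]!r}") from e


def pam30_similarity(query: str, target: str) -> float:
    """Best ungapped-window PAM30 score of query in target over the query's
    self-score. A verbatim occurrence gives exactly 1.0; because PAM30's
    diagonal dominates its rows, any substitution gives < 1."""
    if len(query) < 1:
        raise InvalidArgumentError("query must be non-empty")
    q = _encode(query)
    t = _encode(target)
    if len(t) < len(q):
        raise InvalidArgumentError("target sequence shorter than query peptide")
    m = pam30_matrix()
    self_score = int(m[q, q].sum())
    n_windows = len(t) - len(q) + 1
    windows = np.lib.stride_tricks.sliding_window_view(t, len(q))
    scores = m[q[None, :], windows].sum(axis=1)
    best = int(scores.max())
    return best / self_score


def unambiguous_peptides(
    peptide_sequences: dict[str, str],
    protein_sequences: dict[str, str],
    tol: float = 1e-12,
) -> list[str]:
    """Peptide ids whose best similarity against the target proteins is
    exactly 1 (within floating tolerance): unambiguous phosphosite matches."""
    kept = []
    for pid, seq in peptide_sequences.items():
        best = max(
            (pam30_similarity(seq, prot) for prot in protein_sequences.values()
             if len(prot) >= len(seq)),
            default=0.0,
        )
        if best >= 1.0 - tol:
            kept.append(pid)
    return kept


def _group_mask(labels, groups: tuple[str, str] | None):
    labels = np.asarray(labels)
    if groups is None:
        groups = tuple(sorted(pd.unique(labels)))
    if len(groups) != 2 or set(labels) - set(groups):
        raise InvalidArgumentError(f"labels must take exactly the two values {groups}")
    return labels == groups[1], groups


def peptide_effects(values: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    """Standardized mean difference (group2 - group1)/pooled SD per column.

    Columns with zero pooled SD come back NaN (callers skip them with a
    warning)."""
    g1 = values[~mask2]
    g2 = values[mask2]
    n1, n2 = len(g1), len(g2)
    v1 = g1.var(axis=0, ddof=1)
    v2 = g2.var(axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = (g2.mean(axis=0) - g1.mean(axis=0)) / pooled
    return np.where(pooled == 0, np.nan, eff)


def _effects_many(values: np.ndarray, masks2: np.ndarray) -> np.ndarray:
    """Standardized effects for many group assignments at once.

    ``masks2`` is (B, n) boolean; returns (B, p). All assignments must keep
    both group sizes fixed (true for label permutations)."""
    n = values.shape[0]
    n2 = int(masks2[0].sum())
    n1 = n - n2
    M2 = masks2.astype(float)
    M1 = 1.0 - M2
    s2 = M2 @ values
    s1 = M1 @ values
    ss2 = M2 @ (values**2)
    ss1 = M1 @ (values**2)
    m2 = s2 / n2
    m1 = s1 / n1
    v2 = (ss2 - n2 * m2**2) / (n2 - 1)
    v1 = (ss1 - n1 * m1**2) / (n1 - 1)
    pooled = np.sqrt(np.maximum(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = (m2 - m1) / pooled
    return np.where(pooled == 0, np.nan, eff)


def _substrate_columns(matrix: pd.DataFrame, substrate_set) -> list:
    subs = list(substrate_set)
    if not subs:
        raise InvalidArgumentError("empty substrate set")
    missing = set(subs) - set(matrix.columns)
    if missing:
        raise InvalidArgumentError(
            f"substrates not among the filtered peptides: {sorted(missing)[:5]}"
        )
    return subs


def kinase_statistic(
    matrix: pd.DataFrame, labels, substrate_set, groups: tuple[str, str] | None = None
) -> float:
    """Mean standardized change over the kinase's substrate peptides.

    Positive means higher signal in group 2 (sorted label order by default).
    """
    subs = _substrate_columns(matrix, substrate_set)
    mask2, _ = _group_mask(labels, groups)
    eff = peptide_effects(matrix[subs].to_numpy(dtype=float), mask2)
    if np.isnan(eff).any():
        logger.warning(
            "%d substrate peptide(s) with zero pooled SD skipped", int(np.isnan(eff).sum())
        )
    return float(np.nanmean(eff))


def _perm_masks(mask2: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    order = np.argsort(rng.random((B, mask2.size)), axis=1)
    return mask2[order]


def significance_score(
    matrix: pd.DataFrame,
    labels,
    substrate_set,
    B: int = DEFAULT_B,
    seed: int = 0,
    groups: tuple[str, str] | None = None,
) -> float:
    """-log10 p of the kinase statistic under sample-label permutation.

    Two-sided with the +1 correction: p = (1 + #{|null| >= |observed|}) /
    (B + 1), so the score is bounded by log10(B + 1)."""
    if B < 1:
        raise InvalidArgumentError("B must be >= 1")
    subs = _substrate_columns(matrix, substrate_set)
    mask2, _ = _group_mask(labels, groups)
    values = matrix[subs].to_numpy(dtype=float)
    observed = float(np.nanmean(peptide_effects(values, mask2)))
    rng = np.random.default_rng(seed)
    null = np.nanmean(_effects_many(values, _perm_masks(mask2, B, rng)), axis=1)
    p = (1 + int((np.abs(null) >= abs(observed)).sum())) / (B + 1)
    return -float(np.log10(p))


def specificity_score(
    matrix: pd.DataFrame,
    labels,
    substrate_set,
    B: int = DEFAULT_B,
    seed: int = 0,
    groups: tuple[str, str] | None = None,
) -> float:
    """-log10 p of the kinase statistic against random same-size peptide
    sets drawn (without replacement) from the filtered peptides."""
    if B < 1:
        raise InvalidArgumentError("B must be >= 1")
    subs = _substrate_columns(matrix, substrate_set)
    if len(subs) > matrix.shape[1]:
        raise InvalidArgumentError("substrate set larger than the filtered peptide set")
    mask2, _ = _group_mask(labels, groups)
    all_eff = peptide_effects(matrix.to_numpy(dtype=float), mask2)
    col_idx = {c: i for i, c in enumerate(matrix.columns)}
    # sorted index order everywhere so identical peptide *sets* produce
    # bit-identical means (same float summation order)
    observed = float(np.nanmean(all_eff[np.sort([col_idx[s] for s in subs])]))
    rng = np.random.default_rng(seed)
    k = len(subs)
    draws = np.sort(np.argsort(rng.random((B, matrix.shape[1])), axis=1)[:, :k], axis=1)
    null = np.nanmean(all_eff[draws], axis=1)
    p = (1 + int((np.abs(null) >= abs(observed)).sum())) / (B + 1)
    return -float(np.log10(p))


@dataclass
class KinaseRanking:
    table: pd.DataFrame  # one KinaseScoreRow per kinase, ranked
    skipped: list[str]  # kinases with too few mapped filtered peptides


def rank_kinases(
    matrix: pd.DataFrame,
    labels,
    kinase_map: pd.DataFrame,
    B: int = DEFAULT_B,
    ladder: tuple[int, ...] = DEFAULT_LADDER,
    min_substrates: int = DEFAULT_MIN_SUBSTRATES,
    seed: int = 0,
    groups: tuple[str, str] | None = None,
) -> KinaseRanking:
    """Score and rank every kinase with enough mapped filtered peptides.

    For each kinase the statistic, significance score, and specificity
    score are computed on top-k substrate sets (k over the ladder, by
    mapping confidence rank, truncated to the available substrates) and
    averaged across the ladder; the kinase score is the sum of the two mean
    scores. Sorted by kinase score descending, ties broken by kinase id.
    """
    restricted = kinase_map[kinase_map["peptide_id"].isin(matrix.columns)]
    if restricted.empty:
        raise InvalidArgumentError("no kinase-substrate mappings overlap the peptide matrix")
    rows = []
    skipped = []
    for i, (kin, sub) in enumerate(sorted(restricted.groupby("kinase_id"))):
        subs_ranked = list(sub.sort_values(["rank", "peptide_id"])["peptide_id"])
        n = len(subs_ranked)
        if n < min_substrates:
            skipped.append(kin)
            continue
        ks = sorted({min(k, n) for k in ladder})
        stats_, sigs, specs = [], [], []
        for j, k in enumerate(ks):
            top = subs_ranked[:k]
            stats_.append(kinase_statistic(matrix, labels, top, groups))
            sigs.append(
                significance_score(matrix, labels, top, B, seed=[seed, i, j, 0], groups=groups)
            )
            specs.append(
                specificity_score(matrix, labels, top, B, seed=[seed, i, j, 1], groups=groups)
            )
        sig, spec = float(np.mean(sigs)), float(np.mean(specs))
        rows.append(
            {
                "kinase_id": kin,
                "kinase_statistic": float(np.mean(stats_)),
                "significance_score": sig,
                "specificity_score": spec,
                "kinase_score": sig + spec,
                "n_substrates": n,
            }
        )
    if skipped:
        logger.info(
            "skipped %d kinase(s) with < %d mapped filtered peptides: %s",
            len(skipped), min_substrates, ", ".join(skipped),
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(
            ["kinase_score", "kinase_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        table["rank_position"] = np.arange(1, len(table) + 1)
    return KinaseRanking(table=table, skipped=skipped)


def emit_kinome_table(ranking: pd.DataFrame) -> pd.DataFrame:
    """Flat annotation table for external kinome-tree renderers (CORAL-style):
    branch/node color from the kinase statistic, node size from the kinase
    score. No rendering is performed here."""
    if ranking.empty:
        raise InvalidArgumentError("empty kinase ranking")
    return pd.DataFrame(
        {
            "kinase_id": ranking["kinase_id"],
            "color_value": ranking["kinase_statistic"],
            "size_value": ranking["kinase_score"],
        }
    )
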