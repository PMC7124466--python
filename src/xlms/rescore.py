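"""Semi-supervised target-decoy rescoring and result aggregation.

Given a PIN table of crosslink PSMs (targets and decoys sharing one
feature space), a Percolator-style procedure learns a linear discriminant
by iteratively relabelling confident targets as positives and all decoys
as negatives, inside a cross-validation loop so no PSM is scored by a
model trained on it.  q-values come from target-decoy competition with
the conservative (decoys + 1) / targets estimator.  Accepted PSMs are
aggregated into unique residue-residue links and protein-protein
interaction records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .features import FEATURE_COLUMNS
from .search import CrosslinkPSM

logger = logging.getLogger(__name__)

LINK_TYPES = ("inter", "intra", "loop", "single")


@dataclass
class RescoreResult:
    spec_id: str
    discriminant_score: float
    q_value: float
    accepted: bool
    link_type: str
    is_decoy: bool


def tdc_qvalues(scores: Sequence[float], is_decoy: Sequence[bool]) -> np.ndarray:
    """Target-decoy competition q-values, aligned with the input order.

    PSMs are sorted by descending score (decoys first on ties, the
    conservative choice); at each target the estimated FDR is
    ``(decoys_above + 1) / max(1, targets_above)`` and q-values are the
    running minimum taken from the worst score upward.  Decoys receive
    the q-value of the nearest better-scoring target (1.0 if none).
    """
    scores = np.asarray(scores, dtype=float)
    decoy = np.asarray(is_decoy, dtype=bool)
    if scores.size == 0 or decoy.all():
        raise ValueError("q-value estimation requires at least one target PSM")
    order = np.lexsort((~decoy, -scores))  # descending score, decoys first on ties
    q_sorted = np.empty(scores.size, dtype=float)
    fdr = np.empty(scores.size, dtype=float)
    n_decoys = n_targets = 0
    last_target_fdr = 1.0
    for rank, idx in enumerate(order):
        if decoy[idx]:
            n_decoys += 1
            fdr[rank] = last_target_fdr
        else:
            n_targets += 1
            last_target_fdr = (n_decoys + 1) / max(1, n_targets)
            fdr[rank] = last_target_fdr
    running_min = np.minimum.accumulate(np.minimum(fdr, 1.0)[::-1])[::-1]
    # decoys take the q of the next better target
    q_of_better = 1.0
    for rank, idx in enumerate(order):
        if decoy[idx]:
            q_sorted[rank] = q_of_better
        else:
            q_sorted[rank] = running_min[rank]
            q_of_better = running_min[rank]
    q = np.empty(scores.size, dtype=float)
    q[order] = q_sorted
    return q


def _feature_matrix(pin: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in FEATURE_COLUMNS if c in pin.columns]
    if not cols:
        cols = [
            c for c in pin.columns
            if c not in ("SpecId", "Label", "ScanNr", "Peptide", "Proteins")
        ]
    X = pin[cols].to_numpy(dtype=float)
    keep, kept_cols = [], []
    for j, c in enumerate(cols):
        if np.ptp(X[:, j]) > 0:
            keep.append(j)
            kept_cols.append(c)
        else:
            logger.warning("dropping constant feature %r", c)
    return X[:, keep], kept_cols


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _count_accepted(scores: np.ndarray, decoy: np.ndarray, q_thr: float) -> int:
    q = tdc_qvalues(scores, decoy)
    return int(((q <= q_thr) & ~decoy).sum())


def _initial_direction(
    X: np.ndarray, decoy: np.ndarray, q_init: float
) -> tuple[int, float]:
    """(feature index, sign) maximizing targets accepted at q <= q_init."""
    best = (-1, 0, 1.0)  # n_accepted, feature, sign
    for j in range(X.shape[1]):
        for sign in (1.0, -1.0):
            n = _count_accepted(sign * X[:, j], decoy, q_init)
            if n > best[0]:
                best = (n, j, sign)
    return best[1], best[2]


def semi_supervised_rescore(
    pin: pd.DataFrame,
    n_folds: int = 3,
    n_iters: int = 10,
    q_init: float = 0.01,
    rng_seed: int = 0,
    alpha: float = 1.0,
    min_class_size: int = 20,
) -> pd.DataFrame:
    """Percolator-style iterative linear rescoring with cross-validation.

    Features are standardized; the starting score is the single feature
    (and sign) that accepts the most targets at ``q_init``.  Within each
    training split the procedure alternates: take targets at q <= q_init
    as positives and all decoys as negatives, fit a ridge-regularized
    least-squares discriminant, rescore.  Held-out folds are scored by
    their training model and calibrated against the training decoy score
    distribution before merging.  With fewer than ``min_class_size``
    targets or decoys the initial single-feature ranking is used as-is.

    Returns a copy of ``pin`` with ``discriminant_score`` and ``q_value``
    columns (q-values pooled across link types; see
    :func:`filter_at_fdr` for stratified filtering).
    """
    rng = np.random.default_rng(rng_seed)
    out = pin.reset_index(drop=True).copy()
    decoy = (out["Label"].to_numpy() == -1)
    X_raw, cols = _feature_matrix(out)
    X = _standardize(X_raw)
    n = len(out)
    j0, sign0 = _initial_direction(X, decoy, q_init)
    init_scores = sign0 * X[:, j0]

    n_targets = int((~decoy).sum())
    n_decoys = int(decoy.sum())
    if n_targets < min_class_size or n_decoys < min_class_size or n_iters == 0:
        if n_iters != 0:
            logger.warning(
                "too few targets (%d) or decoys (%d) for semi-supervised "
                "rescoring; falling back to best single feature",
                n_targets, n_decoys,
            )
        final_scores = init_scores
    else:
        final_scores = np.zeros(n)
        fold = rng.permutation(n) % n_folds
        for f in range(n_folds):
            train = fold != f
            test = ~train
            Xtr, dtr = X[train], decoy[train]
            scores = init_scores[train].copy()
            n_init = _count_accepted(scores, dtr, q_init)
            best_model, best_n = None, n_init
            for _ in range(n_iters):
                q = tdc_qvalues(scores, dtr)
                pos = (~dtr) & (q <= q_init)
                if pos.sum() < 2:
                    # too few confident positives to fit: seed from the
                    # top-ranked targets instead
                    t_idx = np.where(~dtr)[0]
                    top = t_idx[np.argsort(-scores[t_idx])][: max(10, len(t_idx) // 20)]
                    pos = np.zeros_like(dtr)
                    pos[top] = True
                idx = np.concatenate([np.where(pos)[0], np.where(dtr)[0]])
                y = np.concatenate([np.ones(int(pos.sum())), -np.ones(int(dtr.sum()))])
                model = Ridge(alpha=alpha).fit(Xtr[idx], y)
                scores = model.predict(Xtr)
                n_acc = _count_accepted(scores, dtr, q_init)
                if n_acc >= best_n:
                    best_model, best_n = model, n_acc
            if best_model is None:
                # learned models never beat the starting feature on this
                # training split; keep the initial direction for the fold
                final_scores[test] = init_scores[test]
                continue
            train_scores = best_model.predict(Xtr)
            test_scores = best_model.predict(X[test])
            # calibrate against the training decoy distribution so folds merge
            d_mu = train_scores[dtr].mean()
            d_sd = train_scores[dtr].std() or 1.0
            final_scores[test] = (test_scores - d_mu) / d_sd
    out["discriminant_score"] = final_scores
    out["q_value"] = tdc_qvalues(final_scores, decoy)
    out["is_decoy"] = decoy
    if "link_type" not in out.columns:
        out["link_type"] = _derive_link_type(out)
    return out


def _derive_link_type(df: pd.DataFrame) -> pd.Series:
    types = pd.Series("inter", index=df.index)
    for t in ("intra", "loop", "single"):
        col = f"is_{t}"
        if col in df.columns:
            types[df[col] == 1] = t
    return types


def filter_at_fdr(
    results: pd.DataFrame,
    threshold: float = 0.02,
    stratified: bool = True,
) -> pd.DataFrame:
    """Accept target PSMs at q <= threshold (inclusive).

    With ``stratified=True`` q-values are recomputed within each link-type
    stratum (inter, intra, loop, single each compete against their own
    decoys) before filtering; otherwise the pooled q-values are used.
    Returns the accepted target rows with a ``q_value`` column.
    """
    if results.empty:
        return results.copy()
    df = results.copy()
    if stratified and "link_type" in df.columns:
        q = pd.Series(np.ones(len(df)), index=df.index)
        for _, idx in df.groupby("link_type").groups.items():
            sub = df.loc[idx]
            if (~sub["is_decoy"]).sum() == 0:
                continue
            q.loc[idx] = tdc_qvalues(
                sub["discriminant_score"].to_numpy(),
                sub["is_decoy"].to_numpy(),
            )
        df["q_value"] = q
    accepted = df[(df["q_value"] <= threshold) & (~df["is_decoy"])]
    return accepted.copy()


def rescore_results(df: pd.DataFrame, threshold: float = 0.02) -> list[RescoreResult]:
    return [
        RescoreResult(
            spec_id=str(row.get("SpecId", i)),
            discriminant_score=float(row["discriminant_score"]),
            q_value=float(row["q_value"]),
            accepted=bool(row["q_value"] <= threshold and not row["is_decoy"]),
            link_type=str(row.get("link_type", "inter")),
            is_decoy=bool(row["is_decoy"]),
        )
        for i, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Aggregation to residue links and protein-protein interactions


@dataclass
class ResidueLink:
    """A unique residue-residue crosslink in protein coordinates."""

    protein_a: str
    site_a: int  # 1-based protein position
    protein_b: str
    site_b: int
    kind: str  # inter | intra
    ambiguous: bool = False
    n_psms: int = 0
    peptide_pairs: set = field(default_factory=set)
    fractions: list = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.protein_a, self.site_a, self.protein_b, self.site_b)


@dataclass
class PPIRecord:
    """Aggregated evidence for one unordered protein pair."""

    protein_a: str
    protein_b: str
    n_psms_total: int
    n_unique_residue_pairs: int
    n_unique_peptide_pairs: int
    n_psms_per_fraction: dict


def _protein_site(peptide, site: int) -> int:
    # site 0 denotes the peptide N terminus (protein N-terminal linkage)
    return peptide.start_pos + max(site, 1) - 1


def aggregate_links(
    psms: Sequence[CrosslinkPSM],
    fractions: Sequence[str] | None = None,
) -> list[ResidueLink]:
    """Collapse accepted PSMs to unique residue-pair links.

    The link key is (proteinA, siteA, proteinB, siteB) in canonical
    (sorted) order; inter if the proteins differ, intra otherwise
    (loop-links are intra by construction).  Dead-end species carry no
    residue pair and are skipped.  A peptide whose protein field is a
    semicolon-joined group is kept but flagged ambiguous.
    """
    links: dict[tuple, ResidueLink] = {}
    fractions = list(fractions) if fractions is not None else [
        p.fraction or "default" for p in psms
    ]
    for psm, fraction in zip(psms, fractions):
        s = psm.species
        if s.kind == "single":
            continue
        pep_b = s.peptide_b if s.peptide_b is not None else s.peptide_a
        site_b = s.site_b
        prot_a, pos_a = s.peptide_a.protein_id, _protein_site(s.peptide_a, s.site_a)
        prot_b, pos_b = pep_b.protein_id, _protein_site(pep_b, site_b)
        if (prot_a, pos_a) > (prot_b, pos_b):
            prot_a, pos_a, prot_b, pos_b = prot_b, pos_b, prot_a, pos_a
        kind = "inter" if prot_a != prot_b else "intra"
        key = (prot_a, pos_a, prot_b, pos_b)
        link = links.get(key)
        if link is None:
            link = ResidueLink(
                protein_a=prot_a, site_a=pos_a,
                protein_b=prot_b, site_b=pos_b,
                kind=kind,
                ambiguous=(";" in prot_a) or (";" in prot_b),
            )
            links[key] = link
        link.n_psms += 1
        pep_pair = tuple(sorted([s.peptide_a.sequence, pep_b.sequence]))
        link.peptide_pairs.add(pep_pair)
        link.fractions.append(fraction)
    return sorted(links.values(), key=lambda l: (-l.n_psms, l.key))


def aggregate_ppis(links: Sequence[ResidueLink]) -> list[PPIRecord]:
    """One record per unordered protein pair, sorted by total PSM count."""
    by_pair: dict[tuple, list[ResidueLink]] = {}
    for link in links:
        pair = tuple(sorted([link.protein_a, link.protein_b]))
        by_pair.setdefault(pair, []).append(link)
    records = []
    for (a, b), group in by_pair.items():
        per_fraction: dict[str, int] = {}
        pep_pairs = set()
        for link in group:
            for fr in link.fractions:
                per_fraction[fr] = per_fraction.get(fr, 0) + 1
            pep_pairs |= link.peptide_pairs
        records.append(
            PPIRecord(
                protein_a=a,
                protein_b=b,
                n_psms_total=sum(l.n_psms for l in group),
                n_unique_residue_pairs=len(group),
                n_unique_peptide_pairs=len(pep_pairs),
                n_psms_per_fraction=per_fraction,
            )
        )
    records.sort(key=lambda r: (-r.n_psms_total, r.protein_a, r.protein_b))
    return records


def write_links_table(links: Sequence[ResidueLink], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_a": l.protein_a, "site_a": l.site_a,
                "protein_b": l.protein_b, "site_b": l.site_b,
                "link_kind": l.kind, "ambiguous": l.ambiguous,
                "n_psms": l.n_psms,
                "n_peptide_pairs": len(l.peptide_pairs),
            }
            for l in links
        ]
    ).to_csv(path, sep="\t", index=False)


def write_ppi_table(records: Sequence[PPIRecord], path: str | Path) -> None:
    fractions = sorted({f for r in records for f in r.n_psms_per_fraction})
    rows = []
    for r in records:
        row = {
            "protein_a": r.protein_a, "protein_b": r.protein_b,
            "n_psms_total": r.n_psms_total,
            "n_unique_residue_pairs": r.n_unique_residue_pairs,
            "n_unique_peptide_pairs": r.n_unique_peptide_pairs,
        }
        for f in fractions:
            row[f"psms_{f}"] = r.n_psms_per_fraction.get(f, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
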