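"""Ground-truth evaluation of the pipeline on synthetic scenes.

These helpers measure what the pipeline recovers against what the scene
generator knows: cell counts, per-cell intersection-over-union, splitting
of touching pairs, fold-change recovery and the null rejection rate of the
class comparison. They are ordinary package functionality (usable for any
parameter study), and double as the basis of the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CellLabelMap
from .quantify import QuantTable, quantify_scene
from .scenes import SceneSpec, render_class_panel, render_scene
from .segmentation import SegmentationParams, segment_pipeline
from .stats import compare_classes, wilcoxon_rank_sum

__all__ = [
    "match_cells",
    "segmentation_recovery",
    "touching_pair_split_rate",
    "panel_fold_estimates",
    "fold_recovery_rate",
    "null_rejection_rate",
]


def match_cells(truth: CellLabelMap, pred: CellLabelMap) -> pd.DataFrame:
    """Greedy 1–1 match of predicted to truth cells by IoU.

    Returns one row per truth cell: (truth_id, pred_id, iou); unmatched
    truth cells get pred_id 0 and iou 0.
    """
    t, p = truth.labels, pred.labels
    nt, npred = truth.n_cells, pred.n_cells
    inter = np.zeros((nt + 1, npred + 1))
    idx = np.ravel_multi_index((t.ravel(), p.ravel()), (nt + 1, npred + 1))
    counts = np.bincount(idx, minlength=(nt + 1) * (npred + 1))
    inter = counts.reshape(nt + 1, npred + 1).astype(float)
    t_area = inter.sum(axis=1)
    p_area = inter.sum(axis=0)
    iou = np.zeros_like(inter)
    for i in range(1, nt + 1):
        for j in range(1, npred + 1):
            union = t_area[i] + p_area[j] - inter[i, j]
            iou[i, j] = inter[i, j] / union if union > 0 else 0.0
    rows = []
    used: set[int] = set()
    order = np.dstack(np.unravel_index(
        np.argsort(-iou[1:, 1:], axis=None), (nt, npred)))[0] + 1
    matched: dict[int, tuple[int, float]] = {}
    for i, j in order:
        if i in matched or j in used or iou[i, j] <= 0:
            continue
        matched[int(i)] = (int(j), float(iou[i, j]))
        used.add(int(j))
    for i in range(1, nt + 1):
        j, v = matched.get(i, (0, 0.0))
        rows.append({"truth_id": i, "pred_id": j, "iou": v})
    return pd.DataFrame(rows)


def segmentation_recovery(spec: SceneSpec,
                          params: SegmentationParams | None = None
                          ) -> dict[str, float]:
    """Segment one scene and score it against its truth.

    Returns recovered/true cell counts, min/mean per-cell IoU, and the
    relative V error per matched cell (against true_V) as an array.
    """
    stack, truth = render_scene(spec)
    labels = segment_pipeline(stack, params)
    matches = match_cells(truth.truth_labels, labels)
    v_err = []
    if labels.n_cells:
        table = quantify_scene(stack, labels)
        v_by_id = {r.cell_id: r.V for r in table.records}
        for row in matches.itertuples():
            if row.pred_id:
                v_err.append(abs(v_by_id[row.pred_id] - truth.true_V[row.truth_id - 1])
                             / truth.true_V[row.truth_id - 1])
    return {
        "n_true": float(truth.truth_labels.n_cells),
        "n_pred": float(labels.n_cells),
        "min_iou": float(matches["iou"].min()) if len(matches) else 1.0,
        "mean_iou": float(matches["iou"].mean()) if len(matches) else 1.0,
        "v_rel_err": np.asarray(v_err),
    }


def touching_pair_split_rate(spec: SceneSpec,
                             params: SegmentationParams | None = None
                             ) -> float:
    """Fraction of touching pairs whose two true centers land in two
    distinct nonzero predicted labels."""
    if spec.touching_pairs == 0:
        raise ValueError("spec has no touching pairs")
    stack, truth = render_scene(spec)
    labels = segment_pipeline(stack, params)
    ok = 0
    for p in range(spec.touching_pairs):
        (r1, c1), (r2, c2) = truth.true_centers[2 * p], truth.true_centers[2 * p + 1]
        l1 = labels.labels[int(round(r1)), int(round(c1))]
        l2 = labels.labels[int(round(r2)), int(round(c2))]
        if l1 > 0 and l2 > 0 and l1 != l2:
            ok += 1
    return ok / spec.touching_pairs


def panel_fold_estimates(base: SceneSpec, folds: dict[str, float],
                         reference: str, seed: int,
                         params: SegmentationParams | None = None,
                         n_scenes_per_class: int = 1,
                         subtract_background: bool = True) -> dict[str, float]:
    """Run the full pipeline on one synthetic panel; return |fold| per class.

    Background subtraction defaults on here: fold recovery is judged
    against the *signal* ground truth, and an additive offset in V would
    shrink every ratio toward 1 regardless of segmentation quality.
    """
    scenes = render_class_panel(base, folds, n_scenes_per_class, seed=seed,
                                reference=reference)
    table = QuantTable()
    for stack, _ in scenes:
        labels = segment_pipeline(stack, params)
        table.extend(quantify_scene(stack, labels,
                                    subtract_background=subtract_background))
    comps = compare_classes(table, reference)
    return {c.class_label: abs(c.fold_change) for c in comps}


def fold_recovery_rate(true_folds: dict[str, float], reference: str,
                       base: SceneSpec, n_replicates: int, seed: int,
                       rel_tol: float = 0.10,
                       params: SegmentationParams | None = None
                       ) -> tuple[float, pd.DataFrame]:
    """Fraction of (replicate, class) fold estimates within ``rel_tol`` of
    truth over ``n_replicates`` independently seeded panels."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        panel_seed = int(rng.integers(0, 2 ** 31))
        est = panel_fold_estimates(base, true_folds, reference, panel_seed,
                                   params)
        for label, f in true_folds.items():
            if label == reference:
                continue
            truth_mag = f if f >= 1 else 1.0 / f
            rows.append({
                "replicate": rep,
                "class_label": label,
                "true_fold": truth_mag,
                "est_fold": est[label],
                "rel_err": abs(est[label] - truth_mag) / truth_mag,
            })
    frame = pd.DataFrame(rows)
    return float((frame["rel_err"] < rel_tol).mean()), frame


def null_rejection_rate(n_per_class: int, n_replicates: int, seed: int,
                        cv: float = 0.2, alpha: float = 0.05) -> float:
    """Type-I error of the class comparison under the generator's cell model.

    Both classes draw per-cell V from the same lognormal amplitude law
    (fold 1.0); the rate is the fraction of replicates with p < ``alpha``.
    """
    rng = np.random.default_rng(seed)
    s = np.sqrt(np.log1p(cv ** 2))
    rejected = 0
    for _ in range(n_replicates):
        a = np.exp(rng.normal(-0.5 * s * s, s, size=n_per_class))
        b = np.exp(rng.normal(-0.5 * s * s, s, size=n_per_class))
        if wilcoxon_rank_sum(a, b) < alpha:
            rejected += 1
    return rejected / n_replicates
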