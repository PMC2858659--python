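"""Load-specific ROI analysis of band-modulator contrast estimates.

Regions are selected only from the task load contrast (retention
ss5 > ss2, FDR-thresholded and cluster-size filtered) — never from
EEG-BOLD correlation maps, so the subsequent band tests are not circular.
Within each region the per-subject modulator betas are averaged over
voxels for each band and load, paired t-tests compare the two loads, and
the result is a signed significance table (+ / - / 0 with p<0.05 and
p<0.01 tiers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fusion_glm import GLMFit, StatMap, cluster_labels_array, threshold_fdr

__all__ = [
    "ROISet",
    "load_contrast_mask",
    "extract_roi_estimates",
    "paired_band_tests",
    "recovery_report",
    "render_sign_table",
]


@dataclass
class ROISet:
    """Disjoint labelled voxel groups from a thresholded group map."""

    labels: np.ndarray  # integer label image, 0 = background
    table: pd.DataFrame  # label, size, peak_t, peak_index

    @property
    def n_rois(self) -> int:
        return int(self.table.shape[0])

    @property
    def roi_ids(self) -> list[int]:
        return [int(x) for x in self.table["label"]]

    def voxels(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id


def load_contrast_mask(
    group_map: StatMap,
    q: float = 0.005,
    k: int = 27,
    tail: str = "greater",
    connectivity: int = 18,
) -> ROISet:
    """ROIs from the group load contrast: BH-FDR at q, clusters >= k kept."""
    mask = threshold_fdr(group_map, q=q, tail=tail)
    labels, n = cluster_labels_array(mask, connectivity=connectivity)
    rows = []
    out = np.zeros_like(labels)
    new_id = 0
    for lab in range(1, n + 1):
        vox = labels == lab
        size = int(vox.sum())
        if size < k:
            continue
        new_id += 1
        out[vox] = new_id
        idx = np.argwhere(vox)
        vals = group_map.t[vox]
        j = int(np.argmax(np.abs(vals)))
        rows.append((new_id, size, float(vals[j]), tuple(idx[j])))
    table = pd.DataFrame(rows, columns=["label", "size", "peak_t", "peak_index"])
    return ROISet(labels=out, table=table)


def extract_roi_estimates(
    rois: ROISet,
    subject_fits: list[GLMFit],
    bands: tuple[str, ...],
    loads: tuple[str, ...] = ("ss2", "ss5"),
) -> pd.DataFrame:
    """Unweighted ROI means of per-subject band-modulator betas.

    Returns the complete roi x subject x band x load crossing as a tidy
    frame with one ``estimate`` per row.
    """
    rows = []
    for s, fit in enumerate(subject_fits):
        if fit.grid_shape is None or fit.grid_shape != rois.labels.shape:
            raise ValueError("subject fits must share the ROI grid")
        for roi_id in rois.roi_ids:
            vox = rois.voxels(roi_id)
            for band in bands:
                for load in loads:
                    beta = fit.beta_map(f"{load}_mod_{band}")
                    rows.append((roi_id, s, band, load, float(beta[vox].mean())))
    return pd.DataFrame(rows, columns=["roi", "subject", "band", "load", "estimate"])


def paired_band_tests(
    table: pd.DataFrame,
    alpha_tiers: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Paired two-tailed t-tests (ss5 - ss2) per ROI per band.

    Output columns: roi, band, t, p, sign (+ / - / 0), tier
    ('p<0.05' / 'p<0.01' / 'ns'); the sign is 0 exactly when the test is
    not significant at the looser tier (strict inequality at each tier).
    """
    loose, strict = alpha_tiers
    rows = []
    for (roi, band), g in table.groupby(["roi", "band"], sort=False):
        piv = g.pivot(index="subject", columns="load", values="estimate")
        if piv.shape[0] < 2:
            raise ValueError("paired tests need at least 2 subjects")
        diff = (piv["ss5"] - piv["ss2"]).to_numpy()
        sd = diff.std(ddof=1)
        if sd == 0:
            t = np.sign(diff.mean()) * np.inf if diff.mean() != 0 else 0.0
            p = 0.0 if diff.mean() != 0 else 1.0
        else:
            t, p = stats.ttest_rel(piv["ss5"], piv["ss2"])
            t, p = float(t), float(p)
        if p < strict:
            tier = f"p<{strict}"
        elif p < loose:
            tier = f"p<{loose}"
        else:
            tier = "ns"
        sign = "0" if tier == "ns" else ("+" if diff.mean() > 0 else "-")
        rows.append((roi, band, t, p, sign, tier))
    return pd.DataFrame(rows, columns=["roi", "band", "t", "p", "sign", "tier"])


def render_sign_table(effects: pd.DataFrame, bands: tuple[str, ...]) -> str:
    """Plain-text ±/blank grid of the ROI x band sign table."""
    mark = {"p<0.05": {"+": "+", "-": "-"}, "p<0.01": {"+": "++", "-": "--"}}
    lines = ["roi\t" + "\t".join(bands)]
    for roi, g in effects.groupby("roi", sort=True):
        cells = []
        for b in bands:
            row = g[g["band"] == b]
            if row.empty or row["sign"].iloc[0] == "0":
                cells.append("")
            else:
                cells.append(mark[row["tier"].iloc[0]][row["sign"].iloc[0]])
        lines.append(f"{roi}\t" + "\t".join(cells))
    return "\n".join(lines)


def recovery_report(truth, group_mod_masks: dict, group_mod_maps: dict,
                    effects: pd.DataFrame | None, rois: ROISet | None) -> dict:
    """Score analysis output against simulation ground truth.

    Per band: voxel sensitivity and false-positive rate of the thresholded
    load-independent coupling maps, the fraction of detected truth voxels
    whose sign matches the truth coupling sign, and (when the ROI table is
    available) whether the ROI load-effect sign matches sign(δ_b).
    """
    report: dict = {"bands": {}}
    for b in truth.band_names:
        truth_vox = truth.coupling_map[b] != 0
        # voxels carrying only the ss5 coupling increment are genuinely
        # coupled in one load; they belong to neither the hit set nor the
        # null set of the load-averaged map
        ambiguous = (truth.coupling_load_delta[b] != 0) & ~truth_vox
        entry: dict = {}
        if b in group_mod_masks:
            det = np.asarray(group_mod_masks[b], dtype=bool)
            tmap = np.asarray(group_mod_maps[b])
            hits = det & truth_vox
            n_hits = int(hits.sum())
            n_truth = int(truth_vox.sum())
            entry["sensitivity"] = float(n_hits / n_truth) if n_truth else None
            null_vox = ~truth_vox & ~ambiguous
            n_null = int(null_vox.sum())
            entry["false_positive_rate"] = float((det & null_vox).sum() / n_null)
            if n_hits:
                agree = np.sign(tmap[hits]) == np.sign(truth.coupling_map[b][hits])
                entry["sign_agreement"] = float(np.mean(agree))
            else:
                entry["sign_agreement"] = None
        if effects is not None and not effects.empty:
            truth_sign = np.sign(truth.load_effect[b])
            got = effects[effects["band"] == b]
            signs = {"+": 1.0, "-": -1.0, "0": 0.0}
            matches = [signs[s] == truth_sign for s in got["sign"]]
            entry["load_sign_match"] = bool(matches and all(matches))
            entry["truth_load_sign"] = float(truth_sign)
        report["bands"][b] = entry
    report["n_rois"] = 0 if rois is None else rois.n_rois
    return report
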