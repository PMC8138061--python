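"""End-to-end analysis: maps -> ROIs -> feature tables -> ranking curves.

``compute_feature_maps`` runs every model on one DWI volume and returns the
full set of 11 named voxelwise features.  The cohort helpers assemble the
two within-subject classification tables (lesion vs contralateral NAWM,
lesion core vs shell) and the two between-subject tables (lesion and NAWM
regions of high- vs low-lesion-count patients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import roi as roi_mod
from .compartment import build_dictionary, fit_compartments
from .dti import fit_tensor, tensor_scalars
from .features import CORE_SHELL_FEATURES, FEATURE_NAMES, extract_features
from .ml import ic_evaluate, rfe_rank
from .odf import fit_sh_odf, odf_energy
from .phantom import DWIVolume, Subject
from .tracking import streamline_maps, track_fact

__all__ = [
    "compute_feature_maps",
    "subject_rois",
    "cohort_tables",
    "rank_and_evaluate",
]


def compute_feature_maps(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    sh_order: int = 6,
    fa_stop: float = 0.15,
    angle_thresh_deg: float = 35.0,
) -> dict:
    """All 11 voxelwise diffusion features of one subject.

    Returns a dict with keys AD, RD, MD, FA (DTI), ODI, density, diameter,
    ICVF, ODF_energy (ssHARDI) and FDi, FTi (tractography), each a
    ScalarMap on the DWI grid.
    """
    if mask is None:
        mask = np.ones(dwi.shape, dtype=bool)
    tf = fit_tensor(dwi, mask)
    maps = dict(tensor_scalars(tf))

    odf = fit_sh_odf(dwi, mask, sh_order=sh_order)
    maps["ODF_energy"] = odf_energy(odf, mask)

    dictionary = build_dictionary(dwi.gradient_table)
    cm = fit_compartments(dwi, dictionary, tf, mask=mask)
    maps.update(
        {"ODI": cm.ODI, "ICVF": cm.ICVF, "density": cm.density, "diameter": cm.diameter}
    )

    streamlines = track_fact(
        tf, mask, angle_thresh_deg=angle_thresh_deg, fa_stop=fa_stop
    )
    sm = streamline_maps(streamlines, dwi.shape, affine=dwi.affine)
    maps["FDi"] = sm.FDi
    maps["FTi"] = sm.FTi

    assert set(maps) == set(FEATURE_NAMES)
    return maps


@dataclass
class SubjectROIs:
    lesions: roi_mod.ROILabelVolume
    pairs: list[roi_mod.ROIPair]
    cores: dict[int, roi_mod.CoreShell | None]


def subject_rois(truth: dict, voxel_size, min_retention: float = 0.5) -> SubjectROIs:
    """Lesion labels, contralateral NAWM pairs and core/shell splits from a
    subject's ground-truth masks."""
    lesions = roi_mod.label_components(
        truth["lesion_label_volume"] > 0, connectivity=26, voxel_size=voxel_size
    )
    pairs = roi_mod.mirror_nawm(
        lesions, truth["wm_mask"], min_retention=min_retention
    )
    cores = {
        rid: roi_mod.core_shell_split(lesions.mask(rid), rid)
        for rid in range(1, lesions.n_rois + 1)
    }
    return SubjectROIs(lesions=lesions, pairs=pairs, cores=cores)


def cohort_tables(
    subjects: list[Subject], maps_per_subject: list[dict] | None = None
) -> dict[str, pd.DataFrame]:
    """Assemble the four classification tables for a simulated cohort.

    Returns ``lesion_nawm`` (11 features, within-subject pairs),
    ``core_shell`` (9 features), and the between-subject ``between_lesion``
    and ``between_nawm`` tables (11 features, label 1 = high-count group).
    """
    if maps_per_subject is None:
        maps_per_subject = [compute_feature_maps(s.dwi, s.truth["wm_mask"]) for s in subjects]

    ln_samples, cs_samples, bl_samples, bn_samples = [], [], [], []
    tables = {}
    for subj, maps in zip(subjects, maps_per_subject):
        rois = subject_rois(subj.truth, subj.dwi.voxel_size)
        glabel = int(subj.group == "high")
        for pair in rois.pairs:
            if not pair.valid:
                continue
            ln_samples.append((pair.lesion_mask, 1, subj.subject_id, pair.lesion_id))
            ln_samples.append((pair.nawm_mask, 0, subj.subject_id, pair.lesion_id))
            bl_samples.append(
                (pair.lesion_mask, glabel, subj.subject_id, pair.lesion_id)
            )
            bn_samples.append((pair.nawm_mask, glabel, subj.subject_id, pair.lesion_id))
        for rid, cs in rois.cores.items():
            if cs is None:
                continue
            cs_samples.append((cs.core_mask, 1, subj.subject_id, rid))
            cs_samples.append((cs.shell_mask, 0, subj.subject_id, rid))

    def _table(samples, names, maps_list):
        frames = []
        # group samples by subject to use the right maps
        by_subj = {}
        for s in samples:
            by_subj.setdefault(s[2], []).append(s)
        for subj, maps in zip(subjects, maps_list):
            if subj.subject_id in by_subj:
                frames.append(
                    extract_features(maps, by_subj[subj.subject_id], names)
                )
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["subject_id", "roi_id", "label"] + names)
        )

    tables["lesion_nawm"] = _table(ln_samples, FEATURE_NAMES, maps_per_subject)
    tables["core_shell"] = _table(cs_samples, CORE_SHELL_FEATURES, maps_per_subject)
    tables["between_lesion"] = _table(bl_samples, FEATURE_NAMES, maps_per_subject)
    tables["between_nawm"] = _table(bn_samples, FEATURE_NAMES, maps_per_subject)
    return tables


def rank_and_evaluate(
    table: pd.DataFrame,
    feature_names: list[str],
    seed: int = 0,
    n_folds: int = 10,
    n_repeats: int = 10,
):
    """Normalize, rank (SVM-RFE) and evaluate (SVM-IC) one feature table."""
    from .features import minmax_normalize

    norm = minmax_normalize(table, feature_names)
    ranker = rfe_rank(
        norm, feature_names, n_folds=n_folds, n_repeats=n_repeats, seed=seed
    )
    curve = ic_evaluate(
        norm[feature_names].to_numpy(),
        norm["label"].to_numpy(),
        ranker.ranking_order_,
        n_folds=n_folds,
        seed=seed,
    )
    return ranker, curve
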