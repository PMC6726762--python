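"""End-to-end per-image orchestration: preprocess → segment → trace →
detect → quantify.

Every segmented object is accounted for: it either yields a
:class:`~quantafm.afm_io.QuantRecord` or an exclusion entry with a
reason.  Per-object failures are logged, never abort the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .afm_io import AFMImage, PipelineConfig, QuantRecord
from .detect import (
    NucleosomeObject,
    hough_circles,
    match_candidates,
    measure_arms,
    opening_angle_vertex,
    split_arms,
)
from .preprocess import preprocess
from .quantify import quantify_record
from .segment import LabeledObjects, segment
from .trace import trace_object

log = logging.getLogger("quantafm")

#: sensitivity sweep settings; candidates kept when stable across >= 2
SWEEP_SENSITIVITIES = (0.90, 0.93, 0.96)


@dataclass
class PipelineResult:
    records: list[QuantRecord]
    exclusions: dict[int, str]          # label -> reason
    objects: LabeledObjects | None = None
    candidates: list = field(default_factory=list)

    @property
    def n_segmented(self) -> int:
        return (self.objects.n_objects if self.objects is not None else
                len(self.records) + len(self.exclusions))


def _sweep_candidates(img: AFMImage, cfg: PipelineConfig) -> list:
    """Hough candidates stable across ≥ 2 of the sweep sensitivities."""
    runs = [hough_circles(img, cfg.hough_radius_nm, s) for s in SWEEP_SENSITIVITIES]
    min_r_px = cfg.hough_radius_nm[0] / img.nm_per_px
    base = max(runs, key=len)
    stable = []
    for c in base:
        hits = sum(
            any(np.hypot(c.center[0] - o.center[0], c.center[1] - o.center[1]) < min_r_px
                for o in run)
            for run in runs
        )
        if hits >= 2:
            stable.append(c)
    return stable


def run_pipeline(
    image: AFMImage,
    cfg: PipelineConfig,
    sensitivity_sweep: bool = False,
) -> PipelineResult:
    """Analyze one image; returns records plus per-object exclusions."""
    pre = preprocess(image, cfg)
    try:
        objs = segment(pre, cfg)
    except ValueError:  # blank/constant image: nothing to segment
        return PipelineResult([], {}, None)
    if sensitivity_sweep:
        cands = _sweep_candidates(pre, cfg)
    else:
        cands = hough_circles(pre, cfg.hough_radius_nm, cfg.hough_sensitivity)
    pairs, ambiguous = match_candidates(cands, objs, cfg.max_gap_px)
    pair_by_label = {lab: cand for cand, lab in pairs}

    records: list[QuantRecord] = []
    exclusions: dict[int, str] = {}
    for label in range(1, objs.n_objects + 1):
        try:
            if label in ambiguous:
                exclusions[label] = "ambiguous"
                continue
            if label in pair_by_label:
                rec = _nucleosome_record(image.source_id, label,
                                         pair_by_label[label], objs, cfg)
            else:
                rec = _free_dna_record(image.source_id, label, objs, cfg)
            if rec is None:
                exclusions[label] = "unmeasurable"
            else:
                records.append(rec)
        except Exception as exc:  # per-object robustness
            log.warning("object %d failed: %s", label, exc)
            exclusions[label] = f"error: {exc}"
    return PipelineResult(records, exclusions, objs, cands)


def _free_dna_record(source_id: str, label: int, objs: LabeledObjects,
                     cfg: PipelineConfig) -> QuantRecord | None:
    fil, _ = trace_object(objs, label)
    if not fil.backbone:
        return None
    return QuantRecord(
        source_id=source_id,
        object_id=label,
        object_kind="free_dna",
        total_length_nm=fil.corrected_length_nm,
        qc_flags=fil.qc_flags,
    )


def _nucleosome_record(source_id: str, label: int, candidate,
                       objs: LabeledObjects, cfg: PipelineConfig,
                       ) -> QuantRecord | None:
    fil, skel = trace_object(objs, label)
    arms, entries, arm_flags = split_arms(candidate, skel)
    flags = list(arm_flags)
    nobj = NucleosomeObject(candidate, label, qc_flags=arm_flags)
    if len(arms) == 2:
        mask = objs.mask_of(label)
        lengths = measure_arms(arms, mask, objs.nm_per_px)
        nobj.arm_short_nm, nobj.arm_long_nm = sorted(lengths)
        theta, theta_flags = opening_angle_vertex(arms, candidate.center,
                                                  cfg.angle_fit_px)
        flags += list(theta_flags)
        nobj.theta_deg = theta
    rec = QuantRecord(
        source_id=source_id,
        object_id=label,
        object_kind="nucleosome",
        radius_nm=candidate.radius_nm,
        theta_deg=nobj.theta_deg,
        short_arm_nm=nobj.arm_short_nm,
        long_arm_nm=nobj.arm_long_nm,
        qc_flags=tuple(flags),
    )
    if not np.isnan(rec.short_arm_nm):
        rec = quantify_record(rec, cfg)
    return rec
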