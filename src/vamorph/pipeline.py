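"""End-to-end synthetic study orchestration.

``run_study`` drives the full protocol on a simulated cohort: generate
phantoms -> segment -> measure under two independently perturbed raters ->
classify by the three EVA rules -> run the statistical battery -> write
tidy result tables. ``rater_experiment`` repeats the two-rater measurement
over replicate cohorts to characterize the inter-rater reliability of 2D
versus volumetric measurements.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as vstats
from .criteria import (
    CriteriaThresholds,
    classify_cincinnati,
    classify_valvassori,
    classify_volumetric,
)
from .errors import DegenerateDataError, InvalidParameterError, VamorphError
from .morpho import measure_record, skeleton_centerline
from .phantom import (
    CohortMember,
    CohortSpec,
    Landmarks,
    PerturbedLandmarks,
    RaterJitter,
    perturb_for_rater,
    rasterize_phantom,
)
from .segment import CutPlane, SegmentationParams, isolate_va
from .volio import LabelMap, VoxelImage

logger = logging.getLogger("vamorph")

RATERS = ("rater1", "rater2")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run (round-trips via dicts)."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    jitter: RaterJitter = field(default_factory=RaterJitter)
    first_crossing: bool = False
    outdir: str | None = None
    master_seed: int = 0
    log_level: str = "info"

    def __post_init__(self) -> None:
        # one master seed drives cohort generation and rater perturbations
        self.cohort = dataclasses.replace(self.cohort, master_seed=self.master_seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("cohort", "segmentation", "thresholds", "jitter"):
            d[key] = dataclasses.asdict(getattr(self, key))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            c.pop("master_seed", None)
            for tup in ("length_range_mm", "spacing"):
                if tup in c and c[tup] is not None:
                    c[tup] = tuple(c[tup])
            d["cohort"] = CohortSpec(**c)
        if "segmentation" in d:
            s = dict(d["segmentation"])
            if s.get("roi_world") is not None:
                s["roi_world"] = tuple(tuple(p) for p in s["roi_world"])
            d["segmentation"] = SegmentationParams(**s)
        if "thresholds" in d:
            d["thresholds"] = CriteriaThresholds(**d["thresholds"])
        if "jitter" in d:
            d["jitter"] = RaterJitter(**d["jitter"])
        return cls(**d)


# ---------------------------------------------------------------------------
# single-ear measurement under one rater
# ---------------------------------------------------------------------------

def measure_ear(
    image: VoxelImage,
    perturbed: PerturbedLandmarks,
    seg_params: SegmentationParams,
    *,
    ear_id: str = "",
    rater_id: str = "",
    first_crossing: bool = False,
    snap_mm: float = 0.0,
):
    """Segment and measure one ear as seen by one rater."""
    lm = perturbed.landmarks
    va = isolate_va(
        image,
        seg_params,
        lm.seed_point,
        CutPlane(tuple(lm.vestibule_exit), tuple(lm.exit_normal)),
        CutPlane(tuple(lm.operculum), tuple(lm.operculum_normal)),
        snap_mm=snap_mm,
    )
    centerline = skeleton_centerline(va, lm.vestibule_exit, lm.operculum)
    record = measure_record(
        image,
        va,
        centerline,
        ear_id=ear_id,
        rater_id=rater_id,
        angle_offset_mid_deg=perturbed.angle_offset_mid_deg,
        angle_offset_oper_deg=perturbed.angle_offset_oper_deg,
        slice_offset_mid=perturbed.slice_offset_mid,
        slice_offset_oper=perturbed.slice_offset_oper,
        first_crossing=first_crossing,
    )
    return record, va


def _identity_perturbation(landmarks: Landmarks) -> PerturbedLandmarks:
    return PerturbedLandmarks(landmarks=landmarks)


def _rater_seed(master_seed: int, ear_index: int, rater_index: int) -> int:
    ss = np.random.SeedSequence([master_seed, 7919, ear_index, rater_index])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# study result
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """All tables of one study run."""

    cohort_table: pd.DataFrame
    descriptives: pd.DataFrame
    group_tests: dict
    correlations: pd.DataFrame
    reliability: dict
    roc: dict | None
    concordance: dict

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cohort_table.to_csv(outdir / "cohort.csv", index=False)
        self.descriptives.to_csv(outdir / "descriptives.csv", index=False)
        self.correlations.to_csv(outdir / "correlations.csv", index=False)
        summary = {
            "group_tests": self.group_tests,
            "reliability": self.reliability,
            "roc": self.roc,
            "concordance": self.concordance,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        return outdir


def _classify_row(rec, thresholds: CriteriaThresholds) -> dict:
    cin = classify_cincinnati(
        rec.midpoint_diameter_mm, rec.operculum_diameter_mm, thresholds
    )
    return {
        "cincinnati_enlarged": cin.enlarged,
        "cincinnati_trigger": cin.trigger,
        "valvassori_enlarged": classify_valvassori(rec.midpoint_diameter_mm, thresholds),
        "volumetric_enlarged": classify_volumetric(rec.mesh_volume_mm3, thresholds),
    }


def measure_cohort(
    members: list[CohortMember],
    config: StudyConfig,
    *,
    perturb: bool = True,
) -> pd.DataFrame:
    """Rasterize, segment and measure every ear under both raters."""
    rows = []
    for e_idx, member in enumerate(members):
        try:
            image, _truth_lumen, truth = rasterize_phantom(member.spec)
            for r_idx, rater in enumerate(RATERS):
                if perturb:
                    pert = perturb_for_rater(
                        truth.landmarks,
                        config.jitter,
                        _rater_seed(config.master_seed, e_idx, r_idx),
                    )
                else:
                    pert = _identity_perturbation(truth.landmarks)
                # a jittered seed may land just outside a thin duct; allow a
                # re-click within the jitter radius plus half a voxel diagonal
                snap = config.jitter.seed_radius_mm + 0.5 * float(
                    np.linalg.norm(member.spec.spacing)
                )
                rec, _va = measure_ear(
                    image,
                    pert,
                    config.segmentation,
                    ear_id=member.ear_id,
                    rater_id=rater,
                    first_crossing=config.first_crossing,
                    snap_mm=snap if perturb else 0.0,
                )
                row = {
                    "ear_id": member.ear_id,
                    "group": member.group,
                    "rater": rater,
                    "truth_volume_mm3": truth.volume_mm3,
                    "truth_midpoint_mm": truth.midpoint_diameter_mm,
                    "truth_operculum_mm": truth.operculum_diameter_mm,
                    "midpoint_mm": rec.midpoint_diameter_mm,
                    "operculum_mm": rec.operculum_diameter_mm,
                    "voxel_volume_mm3": rec.voxel_volume_mm3,
                    "mesh_volume_mm3": rec.mesh_volume_mm3,
                    "flags": ";".join(rec.flags),
                }
                row.update(_classify_row(rec, config.thresholds))
                rows.append(row)
            logger.info("measured ear %s (%s)", member.ear_id, member.group)
        except VamorphError as exc:
            raise VamorphError(
                f"stage 'measure' failed for ear {member.ear_id}: {exc}"
            ) from exc
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full synthetic study; deterministic given the master seed."""
    from .phantom import sample_cohort

    members = sample_cohort(config.cohort)
    logger.info("sampled cohort of %d ears", len(members))
    table = measure_cohort(members, config)

    r1 = table[table["rater"] == RATERS[0]].set_index("ear_id")

    # five-number descriptive block per group (rater 1)
    desc_rows = []
    for group, sub in r1.groupby("group", sort=False):
        for measure, col in (
            ("operculum_mm", "operculum_mm"),
            ("midpoint_mm", "midpoint_mm"),
            ("mesh_volume_mm3", "mesh_volume_mm3"),
        ):
            mn, q1, med, q3, mx = vstats.five_number_summary(sub[col])
            desc_rows.append(
                {
                    "group": group,
                    "measure": measure,
                    "n": len(sub),
                    "min": mn,
                    "q25": q1,
                    "median": med,
                    "q75": q3,
                    "max": mx,
                }
            )
    descriptives = pd.DataFrame(desc_rows)

    # group differences in volume: KW + Dunn + Hodges-Lehmann vs control
    groups = {g: sub["mesh_volume_mm3"].to_numpy() for g, sub in r1.groupby("group", sort=False)}
    group_tests: dict = {}
    if len(groups) >= 2:
        kw = vstats.kruskal_wallis(groups)
        dunn = vstats.dunn_posthoc(groups)
        hl = {}
        for pair in dunn:
            if pair.p_adjusted < 0.05 and "control" in (pair.group_a, pair.group_b):
                other = pair.group_b if pair.group_a == "control" else pair.group_a
                res = vstats.hodges_lehmann(groups["control"], groups[other])
                hl[other] = {
                    "median_difference_mm3": res.estimate,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
        group_tests = {
            "kruskal_wallis": {"H": kw.statistic, "df": kw.df, "p": kw.p_value},
            "dunn": [
                {
                    "pair": f"{p.group_a}|{p.group_b}",
                    "z": p.z,
                    "p_raw": p.p_raw,
                    "p_adjusted": p.p_adjusted,
                }
                for p in dunn
            ],
            "hodges_lehmann_vs_control": hl,
        }

    # per-group correlations of volume with the two diameters
    corr_rows = []
    for group, sub in r1.groupby("group", sort=False):
        for other, label in (("midpoint_mm", "midpoint"), ("operculum_mm", "operculum")):
            try:
                res = vstats.spearman(sub["mesh_volume_mm3"], sub[other])
                corr_rows.append(
                    {"group": group, "versus": label, "rho": res.rho,
                     "p": res.p_value, "n": res.n}
                )
            except (DegenerateDataError, InvalidParameterError):
                corr_rows.append(
                    {"group": group, "versus": label, "rho": np.nan, "p": np.nan,
                     "n": len(sub)}
                )
    correlations = pd.DataFrame(corr_rows)

    # inter-rater reliability
    reliability = {}
    for label, col in (
        ("volume", "mesh_volume_mm3"),
        ("midpoint", "midpoint_mm"),
        ("operculum", "operculum_mm"),
    ):
        wide = table.pivot(index="ear_id", columns="rater", values=col)
        try:
            reliability[label] = vstats.icc_agreement(wide.to_numpy())
        except DegenerateDataError:
            reliability[label] = None

    # ROC: EVAS vs control on volume (rater 1)
    roc_block = None
    evas = r1[r1["group"] == "EVAS"]["mesh_volume_mm3"].to_numpy()
    ctrl = r1[r1["group"] == "control"]["mesh_volume_mm3"].to_numpy()
    if len(evas) > 0 and len(ctrl) > 0:
        roc = vstats.roc_youden(
            np.concatenate([ctrl, evas]),
            np.concatenate([np.zeros(len(ctrl), bool), np.ones(len(evas), bool)]),
        )
        sens_ci = vstats.binomial_ci(
            int(round(roc.cutoff_sensitivity * len(evas))), len(evas)
        )
        spec_ci = vstats.binomial_ci(
            int(round(roc.cutoff_specificity * len(ctrl))), len(ctrl)
        )
        roc_block = {
            "cutoff_mm3": roc.cutoff,
            "youden": roc.cutoff_youden,
            "sensitivity": roc.cutoff_sensitivity,
            "sensitivity_ci": list(sens_ci),
            "specificity": roc.cutoff_specificity,
            "specificity_ci": list(spec_ci),
            "n_evas": len(evas),
            "n_control": len(ctrl),
        }

    # Cincinnati vs volumetric concordance (rater 1)
    cin = r1["cincinnati_enlarged"].to_numpy(bool)
    vol = r1["volumetric_enlarged"].to_numpy(bool)
    concordance = {
        "both_enlarged": int(np.sum(cin & vol)),
        "cincinnati_only": int(np.sum(cin & ~vol)),
        "volumetric_only": int(np.sum(~cin & vol)),
        "both_normal": int(np.sum(~cin & ~vol)),
        "agreement": float(np.mean(cin == vol)),
    }

    result = StudyResult(
        cohort_table=table,
        descriptives=descriptives,
        group_tests=group_tests,
        correlations=correlations,
        reliability=reliability,
        roc=roc_block,
        concordance=concordance,
    )
    if config.outdir:
        result.write(config.outdir)
    for group, sub in table.groupby("group", sort=False):
        logger.info(
            "group %s: %d ears, %d Cincinnati-enlarged, %d volumetric-enlarged",
            group, sub["ear_id"].nunique(),
            int(sub[sub.rater == RATERS[0]]["cincinnati_enlarged"].sum()),
            int(sub[sub.rater == RATERS[0]]["volumetric_enlarged"].sum()),
        )
    return result


# ---------------------------------------------------------------------------
# replicate reliability experiment
# ---------------------------------------------------------------------------

def rater_experiment(config: StudyConfig, replicates: int) -> pd.DataFrame:
    """Per-replicate ICC(2,1) of the three measurement types.

    Each replicate draws a fresh cohort (seed derived from the master seed)
    and measures it under two independent rater perturbations. Returns one
    row per replicate with columns ``icc_volume``, ``icc_midpoint``,
    ``icc_operculum`` and ``volume_best`` (whether the volumetric ICC
    strictly exceeds both diameter ICCs); degenerate replicates are flagged
    rather than aborted.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for rep in range(replicates):
        rep_config = dataclasses.replace(
            config,
            master_seed=int(
                np.random.SeedSequence([config.master_seed, 104729, rep]).generate_state(1)[0]
                % (2**31)
            ),
        )
        from .phantom import sample_cohort

        members = sample_cohort(rep_config.cohort)
        table = measure_cohort(members, rep_config)
        row: dict = {"replicate": rep, "flagged": False}
        for label, col in (
            ("icc_volume", "mesh_volume_mm3"),
            ("icc_midpoint", "midpoint_mm"),
            ("icc_operculum", "operculum_mm"),
        ):
            wide = table.pivot(index="ear_id", columns="rater", values=col)
            try:
                row[label] = vstats.icc_agreement(wide.to_numpy())
            except (DegenerateDataError, InvalidParameterError):
                row[label] = np.nan
                row["flagged"] = True
        row["volume_best"] = (
            not row["flagged"]
            and row["icc_volume"] > max(row["icc_midpoint"], row["icc_operculum"])
        )
        rows.append(row)
        logger.info("replicate %d: %s", rep, row)
    return pd.DataFrame(rows)


def rater_experiment_summary(table: pd.DataFrame) -> dict:
    """Fraction of replicates where the volumetric ICC wins, with its CI."""
    ok = table[~table["flagged"]]
    n = len(ok)
    wins = int(ok["volume_best"].sum())
    lo, hi = vstats.binomial_ci(wins, n) if n else (0.0, 1.0)
    return {"replicates": n, "volume_best": wins,
            "fraction": wins / n if n else float("nan"),
            "ci_low": lo, "ci_high": hi}
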