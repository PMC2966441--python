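"""End-to-end orchestration: simulate -> preprocess -> decode -> infer -> report.

A *study* mirrors the structure of the original experiment: several
simulated subjects, each with three retinotopic ROIs (V1, V2, V3) modelled
as independent cortical sheets whose ocular-dominance/spatial-frequency
coupling and eye selectivity fall off from V1 to V3, twelve block-design
runs per subject, pattern and univariate eye-of-origin decoding per spatial
frequency with permutation inference, and an utrocular-discrimination
session inside and outside the scanner analysed with signal detection
theory.  Everything derives from one master seed, so a study report is
byte-identical across re-runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as uio
from .behavior import accuracy_by_sf, sdt_analysis
from .decoding import DecodingConfig, loro_cv
from .preprocess import samples_from_runs
from .samples import SFS, condition_label
from .stats import one_sample_t, pearson_test, permutation_test
from .synthetic import (
    BehavioralDesign,
    ExperimentDesign,
    GridSpec,
    ResponseModel,
    VoxelSamplingConfig,
    make_cortical_sheet,
    simulate_behavior,
    simulate_experiment,
)

#: Per-ROI forward-model strength: the OD/sf coupling and the eye
#: selectivity both weaken from V1 to V3 (V3 carries no eye signal).
DEFAULT_ROIS: dict[str, dict[str, float]] = {
    "V1": {"coupling_rho": 0.9, "eye_selectivity": 0.8, "left_eye_offset_delta": 0.03},
    "V2": {"coupling_rho": 0.6, "eye_selectivity": 0.5, "left_eye_offset_delta": 0.0},
    "V3": {"coupling_rho": 0.0, "eye_selectivity": 0.0, "left_eye_offset_delta": 0.0},
}


@dataclass
class StudyConfig:
    """Everything needed to simulate and analyse one full study."""

    n_subjects: int = 8
    rois: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ROIS.items()})
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    model: ResponseModel = field(default_factory=ResponseModel)
    sampling: VoxelSamplingConfig = field(default_factory=VoxelSamplingConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    behavioral: BehavioralDesign = field(default_factory=BehavioralDesign)
    n_voxels_cutoff: int = 100
    n_permutations: int = 1000
    family_size: int = 3
    lag_volumes: int = 1
    dominant_eye: str = "L"
    seed: int = 0

    def to_dict(self) -> dict:
        return uio._jsonable(
            {
                "n_subjects": self.n_subjects,
                "rois": self.rois,
                "design": self.design,
                "model": self.model,
                "sampling": self.sampling,
                "grid": self.grid,
                "behavioral": self.behavioral,
                "n_voxels_cutoff": self.n_voxels_cutoff,
                "n_permutations": self.n_permutations,
                "family_size": self.family_size,
                "lag_volumes": self.lag_volumes,
                "dominant_eye": self.dominant_eye,
                "seed": self.seed,
            }
        )

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _sdt_session_responses(stim_eye, sf, behavioral: BehavioralDesign, dominant, rng):
    """Responses of the generative SDT observer to an arbitrary trial list."""
    d = np.array([behavioral.dprime_per_sf[s] for s in sf])
    c = np.array([behavioral.criterion_per_sf[s] for s in sf])
    x = np.where(stim_eye == dominant, d, 0.0) + rng.standard_normal(len(sf))
    say_dom = x > (c + d / 2.0)
    other = "R" if dominant == "L" else "L"
    return np.where(say_dom, dominant, other).astype(object)


def _simulate_in_scanner_behavior(config: StudyConfig, subject_id, rng):
    """One behavioral trial per stimulation block across the 12 runs."""
    from .behavior import BehavioralSession

    stim, sfs = [], []
    for _ in range(config.design.n_runs):
        order = rng.permutation(len(config.design.conditions))
        for i in order:
            eye, sf = config.design.conditions[i].split("_")
            stim.append(eye)
            sfs.append(sf)
    stim = np.array(stim, dtype=object)
    sfs = np.array(sfs, dtype=object)
    resp = _sdt_session_responses(stim, sfs, config.behavioral, config.dominant_eye, rng)
    return BehavioralSession(
        stimulus_eye=stim,
        sf=sfs,
        response_eye=resp,
        dominant_eye=config.dominant_eye,
        subject_id=subject_id,
    )


def _decode_entry(samples, problem, classifier, config: StudyConfig, perm_seed):
    dcfg = DecodingConfig(
        n_voxels_cutoff=config.n_voxels_cutoff, classifier=classifier, problem=problem
    )
    result = loro_cv(samples, dcfg)
    perm = permutation_test(
        samples,
        dcfg,
        n_permutations=config.n_permutations,
        seed=perm_seed,
        family_size=config.family_size,
    )
    return {
        "accuracy": result.accuracy,
        "fold_accuracies": [float(a) for a in result.fold_accuracies],
        "p_value": perm.p_value,
        "corrected_p": perm.corrected_p,
        "n_permutations": perm.n_permutations,
    }


def run_study(config: StudyConfig | None = None) -> dict:
    """Run the full simulated study and return the (JSON-ready) report."""
    config = config or StudyConfig()
    ss = np.random.SeedSequence(config.seed)
    subject_seeds = ss.spawn(config.n_subjects)

    report: dict = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "subjects": {},
    }
    acc_store: dict = {}  # (roi, sf, classifier) -> per-subject accuracies
    beh_out_acc: dict[str, list[float]] = {s: [] for s in SFS}
    beh_in_acc: dict[str, list[float]] = {s: [] for s in SFS}
    beh_d: dict[str, list[float]] = {s: [] for s in SFS}
    beh_c: dict[str, list[float]] = {s: [] for s in SFS}

    for s_idx, s_seed in enumerate(subject_seeds):
        sid = f"sub-{s_idx + 1:02d}"
        roi_seeds = s_seed.spawn(len(config.rois) + 2)
        subject_report: dict = {"rois": {}}
        for (roi, pars), r_seed in zip(config.rois.items(), roi_seeds):
            sheet_seed, sim_seed, perm_seed_seq = r_seed.spawn(3)
            model = replace(
                config.model,
                eye_selectivity=pars.get("eye_selectivity", config.model.eye_selectivity),
                left_eye_offset_delta=pars.get(
                    "left_eye_offset_delta", config.model.left_eye_offset_delta
                ),
            )
            sheet = make_cortical_sheet(
                grid=config.grid,
                coupling_rho=pars.get("coupling_rho", 0.0),
                seed=int(sheet_seed.generate_state(1)[0] % (2**31)),
            )
            runs, _ = simulate_experiment(
                design=config.design,
                sheet=sheet,
                model=model,
                sampling=config.sampling,
                seed=int(sim_seed.generate_state(1)[0] % (2**31)),
            )
            samples = samples_from_runs(runs, lag_volumes=config.lag_volumes)
            roi_report: dict = {}
            perm_seeds = perm_seed_seq.generate_state(4) % (2**31)
            for k, sf in enumerate(SFS):
                problem = (condition_label("L", sf), condition_label("R", sf))
                roi_report[sf] = {
                    "pattern": _decode_entry(
                        samples, problem, "pattern_correlation", config,
                        int(perm_seeds[2 * k]),
                    ),
                    "univariate": _decode_entry(
                        samples, problem, "univariate_difference", config,
                        int(perm_seeds[2 * k + 1]),
                    ),
                }
                for classifier in ("pattern", "univariate"):
                    acc_store.setdefault((roi, sf, classifier), []).append(
                        roi_report[sf][classifier]["accuracy"]
                    )
            subject_report["rois"][roi] = roi_report

        beh_seed, scan_seed = roi_seeds[len(config.rois):]
        out_session = simulate_behavior(
            config.behavioral,
            dominant_eye=config.dominant_eye,
            subject_id=sid,
            seed=int(beh_seed.generate_state(1)[0] % (2**31)),
        )
        in_session = _simulate_in_scanner_behavior(
            config, sid, np.random.default_rng(scan_seed)
        )
        out_acc = accuracy_by_sf(out_session)
        in_acc = accuracy_by_sf(in_session)
        sdt = {sf: sdt_analysis(out_session, sf) for sf in SFS}
        subject_report["behavior"] = {
            "out_of_scanner": {
                "accuracy": out_acc,
                "sdt": {
                    sf: {
                        "dprime": sdt[sf].dprime,
                        "criterion": sdt[sf].criterion,
                        "hit_rate": sdt[sf].hit_rate,
                        "fa_rate": sdt[sf].fa_rate,
                        "correction_applied": sdt[sf].correction_applied,
                    }
                    for sf in SFS
                },
            },
            "in_scanner": {"accuracy": in_acc},
        }
        for sf in SFS:
            beh_out_acc[sf].append(out_acc[sf])
            beh_in_acc[sf].append(in_acc[sf])
            beh_d[sf].append(sdt[sf].dprime)
            beh_c[sf].append(sdt[sf].criterion)
        report["subjects"][sid] = subject_report

    group: dict = {"decoding_vs_chance": {}, "behavior": {}}
    for (roi, sf, classifier), accs in acc_store.items():
        try:
            res = one_sample_t(accs, 0.5)
            entry = {"t": res.statistic, "df": res.df, "p": res.p_two_tailed}
        except ValueError:
            entry = {"t": None, "df": len(accs) - 1, "p": None}
        group["decoding_vs_chance"].setdefault(roi, {}).setdefault(sf, {})[
            classifier
        ] = {**entry, "mean_accuracy": float(np.mean(accs))}

    out_flat = np.concatenate([beh_out_acc[s] for s in SFS])
    in_flat = np.concatenate([beh_in_acc[s] for s in SFS])
    try:
        corr = pearson_test(out_flat, in_flat)
        corr_entry = {
            "r": corr.r,
            "t": corr.statistic,
            "df": corr.df,
            "p": corr.p_two_tailed,
            "n": len(out_flat),
        }
    except ValueError:  # too few subjects or degenerate accuracies
        corr_entry = {"r": None, "t": None, "df": None, "p": None, "n": len(out_flat)}
    group["behavior"] = {
        "accuracy_mean": {s: float(np.mean(beh_out_acc[s])) for s in SFS},
        "accuracy_sem": {
            s: (
                float(np.std(beh_out_acc[s], ddof=1) / np.sqrt(len(beh_out_acc[s])))
                if len(beh_out_acc[s]) > 1
                else None
            )
            for s in SFS
        },
        "dprime_mean": {s: float(np.mean(beh_d[s])) for s in SFS},
        "criterion_mean": {s: float(np.mean(beh_c[s])) for s in SFS},
        "in_out_correlation": corr_entry,
    }
    report["group"] = group
    return report


# --------------------------------------------------------------------------
# Fixture bundles on disk
# --------------------------------------------------------------------------

FIXTURE_SIZES = {
    "tiny": {"n_runs": 3, "extent_mm": 7.5, "n_trials": 48},
    "default": {"n_runs": 12, "extent_mm": 24.0, "n_trials": 624},
}


def make_fixtures(size: str = "tiny", outdir="fixtures", seed: int = 0) -> dict:
    """Write a loadable dataset bundle: NIfTI runs, mask, events, behavior, truth.

    ``tiny`` is a 3-run, ~25-voxel smoke dataset; ``default`` matches the
    full 12-run design.  Identical seeds produce identical files.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SIZES)}")
    spec = FIXTURE_SIZES[size]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    grid = GridSpec(extent_mm=(spec["extent_mm"], spec["extent_mm"]))
    design = ExperimentDesign(n_runs=spec["n_runs"])
    sampling = VoxelSamplingConfig()
    model = ResponseModel()
    sheet = make_cortical_sheet(grid=grid, seed=seed)
    runs, gt = simulate_experiment(
        design=design, sheet=sheet, model=model, sampling=sampling, seed=seed
    )

    paths: dict = {"runs": [], "events": []}
    for run in runs:
        p = uio.write_run_nifti(
            run, gt.voxel_shape, outdir / f"run-{run.run_index + 1:02d}_bold.nii",
            voxel_mm=sampling.voxel_mm,
        )
        e = uio.write_events_tsv(run, outdir / f"run-{run.run_index + 1:02d}_events.tsv")
        paths["runs"].append(p)
        paths["events"].append(e)
    mask = np.ones(gt.voxel_shape, dtype=np.uint8)
    paths["mask"] = uio.write_mask_nifti(
        mask, outdir / "roi_mask.nii", voxel_mm=sampling.voxel_mm
    )

    bdes = BehavioralDesign(n_trials=spec["n_trials"], seed=seed)
    session = simulate_behavior(bdes, seed=seed)
    paths["behavior"] = uio.write_behavior_tsv(session, outdir / "behavior.tsv")

    truth = {
        "seed": seed,
        "size": size,
        "grid": grid,
        "design": design,
        "model": model,
        "sampling": sampling,
        "behavioral": bdes,
        "od_period_mm": sheet.od_period_mm,
        "coupling_rho": sheet.coupling_rho,
        "voxel_shape": list(gt.voxel_shape),
    }
    paths["ground_truth"] = uio.write_json(truth, outdir / "ground_truth.json")
    return paths
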