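"""End-to-end study orchestration: simulate, measure, and test.

Runs the full analysis on synthetic data with a single seed and emits a
report with the figure-shaped comparisons: meristematic vs elongation
distances, the distance–volume correlation, measured vs Monte Carlo null,
the γ-ray dose response with volume invariance and 24-h recovery, the
genotype comparison (a repair-proficient and a repair-deficient
configuration), pairing frequencies per root, and the comet-assay DSB
time course.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import comet as comet_mod
from .morphometry import NucleusMeasurement, correlate_distance_volume, compare_volumes, segment_nucleus
from .shell_null import ShellGeometry, compare_to_null
from .spots import (
    DEFAULT_PAIRING_THRESHOLD_UM,
    detect_foci,
    measure_pair,
    pairing_frequency,
    summarize_distances,
)
from .stack import ImageStack
from .synthetic import (
    CometModel,
    DoseResponseModel,
    NucleusModel,
    SyntheticTruth,
    elongation_model,
    generate_comet_image,
    generate_dose_panel,
    generate_nucleus_stack,
    meristematic_model,
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Everything a study run needs; round-trips losslessly through dicts/YAML."""

    meristematic: NucleusModel = field(default_factory=meristematic_model)
    elongation: NucleusModel = field(default_factory=elongation_model)
    dose_response: DoseResponseModel = field(default_factory=DoseResponseModel)
    shell: ShellGeometry = field(default_factory=lambda: ShellGeometry(r=2.3, r_prime=1.17))
    pairing_threshold_um: float = DEFAULT_PAIRING_THRESHOLD_UM
    spot_sigma_um: tuple[float, float] = (0.3, 0.125)
    min_snr: float = 5.0
    test: str = "welch"
    alpha: float = 0.05
    correction: str = "holm"
    n_zone: int = 30
    doses_gy: tuple[float, ...] = (0.0, 50.0, 100.0, 150.0)
    n_per_dose: int = 25
    recovery_dose_gy: float = 150.0
    recovery_time_h: float = 24.0
    n_recovery: int = 25
    genotype_dose_gy: float = 150.0
    n_roots: int = 5
    n_per_root: int = 30
    comet_n_per_group: int = 20
    comet_fractions: dict = field(
        default_factory=lambda: {"control": 0.05, "0h": 0.5, "24h": 0.08}
    )
    # per-comet tail fractions are Beta-distributed around the group mean
    # with this concentration; comet assays show large cell-to-cell spread
    comet_concentration: float = 4.0
    n_null_pairs: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    # -- genotype switches: no molecular claims, just generator settings --
    def genotype_dose_response(self, genotype: str) -> DoseResponseModel:
        if genotype == "rad54-like":
            return dataclasses.replace(
                self.dose_response, shortening_um=0.0, pairing_boost=0.0
            )
        return self.dose_response

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key, typ in (
            ("meristematic", NucleusModel),
            ("elongation", NucleusModel),
            ("dose_response", DoseResponseModel),
            ("shell", ShellGeometry),
        ):
            if key in d and isinstance(d[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
                }
                d[key] = typ(**sub)
        for key in ("spot_sigma_um", "doses_gy"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Measurement of one synthetic nucleus
# ---------------------------------------------------------------------------

def measure_stack(
    stack: ImageStack,
    truth: SyntheticTruth | None,
    config: StudyConfig,
    nucleus_id: str = "n0",
    root_id: str = "root0",
    with_volume: bool = True,
) -> dict:
    """Detect, pair and (optionally) segment one stack; return a flat record."""
    detections = detect_foci(
        stack, config.spot_sigma_um, min_snr=config.min_snr
    )
    pair = measure_pair(detections, config.pairing_threshold_um)
    row: dict = {
        "nucleus_id": nucleus_id,
        "root_id": root_id,
        "zone": truth.zone if truth else "",
        "dose_gy": truth.dose_gy if truth else np.nan,
        "time_h": truth.time_h if truth else np.nan,
        "genotype": truth.genotype if truth else "",
        "n_candidates": pair.n_candidates if pair else 0,
        "threshold_um": config.pairing_threshold_um,
        "distance_um": pair.distance_um if pair else np.nan,
        "paired": pair.paired if pair else None,
        "measurable": pair is not None,
        "pair": pair,
    }
    if with_volume:
        try:
            _, meas = segment_nucleus(stack, nucleus_id=nucleus_id)
            row["volume_um3"] = meas.volume_um3
            row["clipped"] = meas.clipped
        except Exception:
            row["volume_um3"] = np.nan
            row["clipped"] = True
    if truth is not None:
        row["truth_separation_um"] = truth.separation_um
        row["truth_volume_um3"] = truth.volume_um3
    return row


def _rows_to_measurements(rows: list[dict]) -> list[NucleusMeasurement]:
    out = []
    for r in rows:
        if not r["measurable"] or not np.isfinite(r.get("volume_um3", np.nan)):
            continue
        out.append(
            NucleusMeasurement(
                nucleus_id=r["nucleus_id"],
                volume_um3=r["volume_um3"],
                centroid_um=(0.0, 0.0, 0.0),
                clipped=bool(r.get("clipped", False)),
                zone=r["zone"],
                dose_gy=r["dose_gy"],
                time_h=r["time_h"],
                genotype=r["genotype"],
                distance_um=r["distance_um"],
                paired=r["paired"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Grouped statistics
# ---------------------------------------------------------------------------

def grouped_distance_test(
    groups: dict[str, np.ndarray],
    control: str,
    test: str = "welch",
    alpha: float = 0.05,
    correction: str = "holm",
) -> dict:
    """Pairwise tests of each group against the designated control.

    Raw two-sided p-values are corrected across comparisons (Holm by
    default); significance stars follow the 0.05/0.01 convention and are
    assigned on the corrected p-values.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ctrl = np.asarray(groups[control], dtype=float)
    if ctrl.size < 2:
        raise ValueError("control group needs n >= 2")
    names, raw_p, stats_ = [], [], []
    for name, values in groups.items():
        if name == control:
            continue
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
        if v.std() == 0 and ctrl.std() == 0 and v.mean() == ctrl.mean():
            s, p = 0.0, 1.0
        elif test == "welch":
            s, p = stats.ttest_ind(v, ctrl, equal_var=False)
        elif test == "mannwhitney":
            s, p = stats.mannwhitneyu(v, ctrl, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        names.append(name)
        raw_p.append(float(p))
        stats_.append(float(s))
    if correction == "holm":
        _, corrected, _, _ = multipletests(raw_p, alpha=alpha, method="holm")
    elif correction in (None, "none"):
        corrected = raw_p
    else:
        raise ValueError(f"unknown correction {correction!r}")
    table = {}
    for name, s, p_raw, p_corr in zip(names, stats_, raw_p, corrected):
        stars = "**" if p_corr < 0.01 else "*" if p_corr < 0.05 else ""
        table[name] = {
            "n": int(np.asarray(groups[name]).size),
            "mean": float(np.asarray(groups[name], dtype=float).mean()),
            "statistic": s,
            "p_raw": p_raw,
            "p_corrected": float(p_corr),
            "significant": bool(p_corr < alpha),
            "stars": stars,
        }
    return {
        "control": control,
        "control_n": int(ctrl.size),
        "control_mean": float(ctrl.mean()),
        "test": test,
        "correction": correction,
        "alpha": alpha,
        "comparisons": table,
    }


# ---------------------------------------------------------------------------
# The study
# ---------------------------------------------------------------------------

def _spawn(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def run_study(config: StudyConfig | None = None) -> dict:
    """Execute every stage on generated data and return the study report.

    The report is a plain JSON-serialisable dict; identical config and
    seed give identical reports.
    """
    config = config or StudyConfig()
    seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in _spawn(config.seed, 64))
    report: dict = {"config": config.to_dict(), "seed": config.seed, "verdicts": {}}
    stage = "setup"

    try:
        # ------------------------------------------------------------------
        # Stage 1: zones (distance constancy context + elongation > meristem)
        # ------------------------------------------------------------------
        stage = "zones"
        zone_rows: dict[str, list[dict]] = {}
        for zone, model in (("meristematic", config.meristematic), ("elongation", config.elongation)):
            stage_seed = next(seeds)
            rows = []
            for i, child in enumerate(_spawn(stage_seed, config.n_zone)):
                rng = np.random.default_rng(child)
                stack, truth = generate_nucleus_stack(model, seed=rng)
                rows.append(measure_stack(stack, truth, config, nucleus_id=f"{zone}-{i}"))
            zone_rows[zone] = rows

        zone_summaries = {}
        zone_values = {}
        for zone, rows in zone_rows.items():
            pairs = [r["pair"] for r in rows if r["measurable"]]
            summary = summarize_distances(pairs, exclude_paired=True)
            zone_summaries[zone] = {
                "n": summary.n, "mean_um": summary.mean_um, "sd_um": summary.sd_um,
                "n_paired_excluded": summary.n_excluded_paired,
            }
            zone_values[zone] = summary.values_um
        zone_test = grouped_distance_test(
            zone_values, control="meristematic", test=config.test,
            alpha=config.alpha, correction="none",
        )
        report["zones"] = {"summaries": zone_summaries, "test": zone_test}
        elong = zone_test["comparisons"]["elongation"]
        report["verdicts"]["elongation_longer_than_meristematic"] = bool(
            elong["significant"]
            and zone_summaries["elongation"]["mean_um"] > zone_summaries["meristematic"]["mean_um"]
        )

        # ------------------------------------------------------------------
        # Stage 2: distance-volume correlation (pooled zones)
        # ------------------------------------------------------------------
        stage = "distance_volume"
        all_rows = zone_rows["meristematic"] + zone_rows["elongation"]
        corr = correlate_distance_volume(_rows_to_measurements(all_rows))
        report["distance_volume"] = corr
        report["verdicts"]["distance_volume_positively_correlated"] = bool(
            corr["r"] > 0 and corr["p"] < config.alpha
        )

        # ------------------------------------------------------------------
        # Stage 3: measured vs Monte Carlo shell null (meristematic)
        # ------------------------------------------------------------------
        stage = "null_comparison"
        null_report = compare_to_null(
            zone_values["meristematic"], config.shell,
            n_null_pairs=config.n_null_pairs, seed=next(seeds),
        )
        report["null_comparison"] = null_report
        report["verdicts"]["measured_longer_than_null"] = bool(
            null_report["measured_longer"] and null_report["p_value"] < config.alpha
        )

        # ------------------------------------------------------------------
        # Stage 4: dose response at t = 0, volume invariance
        # ------------------------------------------------------------------
        stage = "dose_response"
        panel = generate_dose_panel(
            config.meristematic, config.dose_response, config.doses_gy,
            config.n_per_dose, time_h=0.0, seed=next(seeds),
        )
        dose_rows = [
            measure_stack(stack, truth, config, nucleus_id=f"dose-{i}")
            for i, (stack, truth) in enumerate(panel)
        ]
        dose_values = {}
        for dose in config.doses_gy:
            pairs = [
                r["pair"] for r in dose_rows
                if r["measurable"] and r["dose_gy"] == dose and not r["pair"].paired
            ]
            dose_values[f"{dose:g}Gy"] = np.array([p.distance_um for p in pairs])
        dose_test = grouped_distance_test(
            dose_values, control=f"{config.doses_gy[0]:g}Gy", test=config.test,
            alpha=config.alpha, correction=config.correction,
        )
        report["dose_response"] = {
            "means_um": {k: float(v.mean()) for k, v in dose_values.items()},
            "test": dose_test,
        }
        top = f"{max(config.doses_gy):g}Gy"
        report["verdicts"]["distance_shortened_at_high_dose"] = bool(
            dose_test["comparisons"][top]["significant"]
            and dose_values[top].mean() < dose_values[f"{config.doses_gy[0]:g}Gy"].mean()
        )

        vol_groups = {}
        for dose in (config.doses_gy[0], max(config.doses_gy)):
            vols = [
                r["volume_um3"] for r in dose_rows
                if r["dose_gy"] == dose and np.isfinite(r.get("volume_um3", np.nan))
                and not r.get("clipped", False)
            ]
            vol_groups[f"{dose:g}Gy"] = np.array(vols)
        vol_test = compare_volumes(vol_groups, test=config.test)
        report["volume_invariance"] = vol_test
        report["verdicts"]["volume_unchanged_by_dose"] = bool(vol_test["p"] >= config.alpha)

        # ------------------------------------------------------------------
        # Stage 5: recovery at 24 h
        # ------------------------------------------------------------------
        stage = "recovery"
        recovery_panel = generate_dose_panel(
            config.meristematic, config.dose_response, [config.recovery_dose_gy],
            config.n_recovery, time_h=config.recovery_time_h, seed=next(seeds),
        )
        rec_rows = [
            measure_stack(stack, truth, config, nucleus_id=f"rec-{i}", with_volume=False)
            for i, (stack, truth) in enumerate(recovery_panel)
        ]
        rec_pairs = [r["pair"] for r in rec_rows if r["measurable"] and not r["pair"].paired]
        rec_values = np.array([p.distance_um for p in rec_pairs])
        rec_test = grouped_distance_test(
            {"baseline": dose_values[f"{config.doses_gy[0]:g}Gy"], "24h": rec_values},
            control="baseline", test=config.test, alpha=config.alpha, correction="none",
        )
        report["recovery"] = {
            "mean_um_24h": float(rec_values.mean()),
            "baseline_mean_um": float(dose_values[f"{config.doses_gy[0]:g}Gy"].mean()),
            "test": rec_test,
        }
        report["verdicts"]["distance_recovered_at_24h"] = bool(
            not rec_test["comparisons"]["24h"]["significant"]
        )

        # ------------------------------------------------------------------
        # Stage 6: genotypes x irradiation, distances and pairing frequency
        # ------------------------------------------------------------------
        stage = "genotypes"
        genotype_section: dict = {}
        geno_values: dict[str, np.ndarray] = {}
        geno_pairing: dict[str, dict] = {}
        for genotype in ("wild-type", "rad54-like"):
            dr = config.genotype_dose_response(genotype)
            for dose in (0.0, config.genotype_dose_gy):
                pairs_by_root = {}
                dists = []
                stage_seed = next(seeds)
                for root_i, root_seed in enumerate(_spawn(stage_seed, config.n_roots)):
                    root_seed_int = int(root_seed.generate_state(1)[0] % 2**31)
                    panel = generate_dose_panel(
                        config.meristematic, dr, [dose], config.n_per_root,
                        time_h=0.0, seed=root_seed_int, genotype=genotype,
                    )
                    root_pairs = []
                    for i, (stack, truth) in enumerate(panel):
                        row = measure_stack(
                            stack, truth, config,
                            nucleus_id=f"{genotype}-{dose:g}-{root_i}-{i}",
                            root_id=f"root{root_i}", with_volume=False,
                        )
                        if row["measurable"]:
                            root_pairs.append(row["pair"])
                            if not row["pair"].paired:
                                dists.append(row["distance_um"])
                    pairs_by_root[f"root{root_i}"] = root_pairs
                key = f"{genotype}:{dose:g}Gy"
                geno_values[key] = np.array(dists)
                geno_pairing[key] = pairing_frequency(pairs_by_root)

        for genotype in ("wild-type", "rad54-like"):
            k0, k1 = f"{genotype}:0Gy", f"{genotype}:{config.genotype_dose_gy:g}Gy"
            dist_test = grouped_distance_test(
                {k0: geno_values[k0], k1: geno_values[k1]}, control=k0,
                test=config.test, alpha=config.alpha, correction="none",
            )
            f0 = np.array(list(geno_pairing[k0]["per_root"].values()))
            f1 = np.array(list(geno_pairing[k1]["per_root"].values()))
            if np.allclose(f0, f1.mean()) and np.allclose(f1, f1.mean()):
                p_pairing = 1.0
            else:
                _, p_pairing = stats.ttest_ind(f1, f0, equal_var=False)
            genotype_section[genotype] = {
                "distance_test": dist_test,
                "pairing": {
                    "0Gy": geno_pairing[k0],
                    "irradiated": geno_pairing[k1],
                    "p": float(p_pairing),
                },
            }
        report["genotypes"] = genotype_section
        wt = genotype_section["wild-type"]
        mut = genotype_section["rad54-like"]
        wt_key = f"wild-type:{config.genotype_dose_gy:g}Gy"
        mut_key = f"rad54-like:{config.genotype_dose_gy:g}Gy"
        report["verdicts"]["wildtype_shortening_after_irradiation"] = bool(
            wt["distance_test"]["comparisons"][wt_key]["significant"]
            and geno_values[wt_key].mean() < geno_values["wild-type:0Gy"].mean()
        )
        report["verdicts"]["rad54_no_shortening"] = bool(
            not mut["distance_test"]["comparisons"][mut_key]["significant"]
        )
        report["verdicts"]["wildtype_pairing_increase"] = bool(
            wt["pairing"]["p"] < config.alpha
            and wt["pairing"]["irradiated"]["mean"] > wt["pairing"]["0Gy"]["mean"]
        )
        report["verdicts"]["rad54_no_pairing_increase"] = bool(
            mut["pairing"]["p"] >= config.alpha
            or mut["pairing"]["irradiated"]["mean"] <= mut["pairing"]["0Gy"]["mean"]
        )
        report["pairing_baseline_percent"] = 100.0 * float(
            np.mean([geno_pairing["wild-type:0Gy"]["mean"], geno_pairing["rad54-like:0Gy"]["mean"]])
        )

        # ------------------------------------------------------------------
        # Stage 7: comet-assay DSB time course
        # ------------------------------------------------------------------
        stage = "comet"
        comet_groups: dict[str, list] = {}
        comet_seed = next(seeds)
        kappa = config.comet_concentration
        for gi, (group, fraction) in enumerate(sorted(config.comet_fractions.items())):
            measurements = []
            for i, child in enumerate(_spawn(comet_seed + gi, config.comet_n_per_group)):
                rng = np.random.default_rng(child)
                if 0 < fraction < 1 and kappa > 0:
                    f_i = float(rng.beta(fraction * kappa, (1.0 - fraction) * kappa))
                else:
                    f_i = fraction
                model = CometModel(tail_fraction=f_i)
                image, _ = generate_comet_image(model, seed=int(rng.integers(2**31)))
                measurements.append(comet_mod.measure_comet(image, condition=group))
            comet_groups[group] = measurements
        comet_report = comet_mod.dsb_timecourse(comet_groups, alpha=config.alpha)
        report["comet"] = {
            "groups": comet_report["groups"],
            "verdict": comet_report["verdict"],
        }
        report["verdicts"]["dsb_recovered_at_24h"] = comet_report["verdict"] == "recovered"
    except Exception as err:  # annotate the failing stage and re-raise
        raise RuntimeError(f"study failed in stage {stage!r}: {err}") from err

    return report


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=1, sort_keys=True, default=_default))
    return path


def _default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
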