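"""Three-arm adaptive-radiotherapy experiment on a synthetic cohort.

Arms
----
pPlan   the initial optimized plan evaluated on the planning anatomy — the
        theoretical plan, untouched by anatomical change.
dPlan   the initial plan held fixed in room coordinates while the anatomy
        shrinks and shifts: per-fraction doses are sampled on each
        fraction's anatomy, warped to the planning frame and accumulated —
        the dose actually delivered.
aPlan   weekly re-optimization on the current anatomy with the until-then
        accumulated dose as background, delivered and accumulated the same
        way.

All metrics are evaluated on the planning-frame structures after
accumulation; for aPlan the conformity index is additionally reported
against the final adapted PTV (``ci_adapted``), since either anchor is
defensible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .accumulation import warp_dose
from .cohort import REFERENCE_GTV_CM3, REFERENCE_PRESCRIPTION_GY
from .course import Course, RegressionParams, simulate_course
from .deform import invert_dvf, warp_mask
from .dose_model import FalloffModel, PlanObjectives, optimize_plan, readapt_plan
from .grid import DoseGrid, GridSpec, Mask, mask_volume
from .phantom import EVAL_LUNG, PhantomSpec, StructureSet, build_phantom
from .radiobiology import (
    DEFAULT_RADIOBIO_PARAMS,
    NiemierkoParams,
    conformity_index,
    dose_at_volume,
    geud,
    homogeneity_index,
    ntcp,
    tcp,
    volume_at_dose,
)
from .stats import wilcoxon_signed_rank

__all__ = [
    "AdaptationSchedule",
    "ScenarioResult",
    "CohortComparison",
    "ExperimentConfig",
    "CohortReport",
    "run_pplan",
    "run_dplan",
    "run_aplan",
    "compare_cohort",
    "run_experiment",
    "evaluate_metrics",
    "HEADLINE_METRICS",
]

SCENARIOS = ("pPlan", "dPlan", "aPlan")

#: Metrics used in the cohort-level pairwise comparisons.
HEADLINE_METRICS = (
    "lung/mean_gy",
    "lung/V20Gy_pct",
    "lung/geud_gy",
    "lung/ntcp_pct",
    "heart/mean_gy",
    "heart/ntcp_pct",
    "esophagus/mean_gy",
    "esophagus/ntcp_pct",
    "spinal_cord/D2pct_gy",
    "spinal_cord/ntcp_pct",
    "PTV/ci",
    "PTV/hi",
    "PTV/geud_gy",
    "PTV/tcp_pct",
)


@dataclass(frozen=True)
class AdaptationSchedule:
    """Which fraction's anatomy each adapted plan is based on.

    ``blocks`` is an ordered list of (source_fraction, fractions_covered):
    source_fraction 0 denotes the initial plan (planning anatomy).  The
    default clinical pattern: initial plan for fraction 1; adapt on the
    fraction-1 image for fractions 2–5; then on fraction 5 for 6–10; on
    fraction 10 for 11–15; and so on every ``interval`` fractions.
    """

    blocks: tuple[tuple[int, tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        covered = [f for _, fr in self.blocks for f in fr]
        if covered != sorted(covered) or len(set(covered)) != len(covered):
            raise ValueError("schedule blocks must partition fractions in order")
        if covered and covered[0] != 1:
            raise ValueError("schedule must start at fraction 1")
        if covered != list(range(1, len(covered) + 1)):
            raise ValueError("schedule blocks must cover 1..N without gaps")

    @property
    def n_fractions(self) -> int:
        return sum(len(fr) for _, fr in self.blocks)

    @classmethod
    def weekly(cls, n_fractions: int, interval: int = 5) -> "AdaptationSchedule":
        blocks: list[tuple[int, tuple[int, ...]]] = [(0, (1,))]
        start = 2
        source = 1
        while start <= n_fractions:
            end = min(start + interval - 1 - (start == 2), n_fractions)
            # first adapted block covers fractions 2..interval (4 fractions),
            # subsequent blocks cover `interval` fractions each
            blocks.append((source, tuple(range(start, end + 1))))
            source = end
            start = end + 1
        return cls(tuple(blocks))

    @classmethod
    def none(cls, n_fractions: int) -> "AdaptationSchedule":
        """No adaptation: the initial plan covers every fraction."""
        return cls(((0, tuple(range(1, n_fractions + 1))),))


@dataclass
class ScenarioResult:
    """Accumulated dose and evaluated metrics for one patient and one arm."""

    scenario: str
    patient_id: str
    accumulated: DoseGrid = field(repr=False)
    metrics: dict[str, float] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for key, value in self.metrics.items():
            structure, metric = key.split("/", 1)
            rows.append(
                {"patient": self.patient_id, "scenario": self.scenario,
                 "structure": structure, "metric": metric, "value": value}
            )
        return rows


def evaluate_metrics(
    dose: DoseGrid,
    planning: StructureSet,
    prescription_gy: float,
    radiobio: dict[str, NiemierkoParams] | None = None,
    piv_fraction: float = 0.95,
    adapted_ptv: Mask | None = None,
) -> dict[str, float]:
    """Full metric bundle on the planning-frame structures.

    Keys are ``structure/metric``; probabilities are in percent, doses in Gy.
    ``adapted_ptv`` adds a separately flagged conformity index against a
    final adapted target.
    """
    rb = radiobio or DEFAULT_RADIOBIO_PARAMS
    piv_dose = piv_fraction * prescription_gy
    out: dict[str, float] = {}

    doses_by_structure = {
        "GTV": dose.in_mask(planning["GTV"]),
        "PTV": dose.in_mask(planning["PTV"]),
        EVAL_LUNG: dose.in_mask(planning.eval_lung()),
        "heart": dose.in_mask(planning["heart"]),
        "esophagus": dose.in_mask(planning["esophagus"]),
        "spinal_cord": dose.in_mask(planning["spinal_cord"]),
    }
    for name, d in doses_by_structure.items():
        out[f"{name}/mean_gy"] = float(d.mean())
        out[f"{name}/D2pct_gy"] = dose_at_volume(d, 2.0)
        out[f"{name}/D95pct_gy"] = dose_at_volume(d, 95.0)
        params = rb.get(name if name != EVAL_LUNG else "lung")
        if params is None:
            continue
        g = geud(d, params.a, clip=True)
        out[f"{name}/geud_gy"] = g
        if params.target:
            out[f"{name}/tcp_pct"] = 100.0 * tcp(g, params.d50, params.y50)
        else:
            out[f"{name}/ntcp_pct"] = 100.0 * ntcp(g, params.d50, params.y50)

    out["lung/V20Gy_pct"] = volume_at_dose(doses_by_structure[EVAL_LUNG], 20.0)
    out["heart/V50Gy_pct"] = volume_at_dose(doses_by_structure["heart"], 50.0)
    ptv_d = doses_by_structure["PTV"]
    out["PTV/hi"] = homogeneity_index(ptv_d)
    out["PTV/ci"] = conformity_index(planning["PTV"], dose, piv_dose)
    if adapted_ptv is not None:
        out["PTV/ci_adapted"] = conformity_index(adapted_ptv, dose, piv_dose)
    return out


def _objectives_for(course: Course) -> PlanObjectives:
    return PlanObjectives(course.prescription_total_gy, course.fraction_dose_gy)


def run_pplan(
    course: Course,
    objectives: PlanObjectives | None = None,
    falloff: FalloffModel = FalloffModel(),
    patient_id: str = "p0",
) -> ScenarioResult:
    """Theoretical plan: initial optimized dose on the planning anatomy."""
    obj = objectives or _objectives_for(course)
    dose = optimize_plan(course.planning, obj, falloff, warn_on_violation=False)
    metrics = evaluate_metrics(dose, course.planning, obj.prescription_total_gy)
    return ScenarioResult("pPlan", patient_id, dose, metrics)


def run_dplan(
    course: Course,
    objectives: PlanObjectives | None = None,
    falloff: FalloffModel = FalloffModel(),
    patient_id: str = "p0",
) -> ScenarioResult:
    """Delivered plan: initial plan fixed in room coordinates, anatomy moving."""
    obj = objectives or _objectives_for(course)
    total = optimize_plan(course.planning, obj, falloff, warn_on_violation=False)
    per_fraction = DoseGrid(total.grid, total.values / course.n_fractions)
    acc = np.zeros(total.grid.shape)
    for rec in course.fractions:
        acc += warp_dose(per_fraction, rec.dvf_to_planning,
                         rec.setup_shift_mm).values
    dose = DoseGrid(total.grid, acc)
    metrics = evaluate_metrics(dose, course.planning, obj.prescription_total_gy)
    return ScenarioResult("dPlan", patient_id, dose, metrics)


def run_aplan(
    course: Course,
    objectives: PlanObjectives | None = None,
    schedule: AdaptationSchedule | None = None,
    falloff: FalloffModel = FalloffModel(),
    patient_id: str = "p0",
) -> ScenarioResult:
    """Adapted plan: weekly re-optimization with background-dose awareness."""
    obj = objectives or _objectives_for(course)
    sched = schedule or AdaptationSchedule.weekly(course.n_fractions)
    if sched.n_fractions != course.n_fractions:
        raise ValueError(
            f"schedule covers {sched.n_fractions} fractions, course has "
            f"{course.n_fractions}"
        )
    grid = course.planning.grid
    initial = optimize_plan(course.planning, obj, falloff, warn_on_violation=False)
    acc = np.zeros(grid.shape)
    delivered = 0
    for source, covered in sched.blocks:
        if source == 0:
            plan = DoseGrid(grid, initial.values / course.n_fractions)
        else:
            rec = course.fractions[source - 1]
            structures_now = rec.structures
            # project the planning-frame background into the current frame
            inv = invert_dvf(rec.dvf_to_planning)
            background = warp_dose(DoseGrid(grid, acc), inv)
            plan = readapt_plan(structures_now, obj, background, delivered,
                                falloff)
        for k in covered:
            rec_k = course.fractions[k - 1]
            acc += warp_dose(plan, rec_k.dvf_to_planning,
                             rec_k.setup_shift_mm).values
            delivered += 1
    dose = DoseGrid(grid, acc)
    metrics = evaluate_metrics(
        dose, course.planning, obj.prescription_total_gy,
        adapted_ptv=course.fractions[-1].structures["PTV"],
    )
    return ScenarioResult("aPlan", patient_id, dose, metrics)


@dataclass
class CohortComparison:
    """Paired cohort comparison of one metric between two arms."""

    metric: str
    scenario_a: str
    scenario_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float | None
    pvalue: float | None
    identical: bool = False

    @property
    def significant(self) -> bool:
        return self.pvalue is not None and self.pvalue < 0.05


def compare_cohort(
    results_a: list[ScenarioResult],
    results_b: list[ScenarioResult],
    metrics: tuple[str, ...] = HEADLINE_METRICS,
) -> list[CohortComparison]:
    """Paired Wilcoxon comparisons per metric, with mean ± sd summaries."""
    ids_a = [r.patient_id for r in results_a]
    ids_b = [r.patient_id for r in results_b]
    if ids_a != ids_b:
        raise ValueError("patient ids differ between the two arms")
    out = []
    for metric in metrics:
        a = np.array([r.metrics[metric] for r in results_a])
        b = np.array([r.metrics[metric] for r in results_b])
        if np.all(a == b):
            cmp_ = CohortComparison(
                metric, results_a[0].scenario, results_b[0].scenario,
                a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1),
                None, None, identical=True,
            )
        else:
            res = wilcoxon_signed_rank(b, a)
            cmp_ = CohortComparison(
                metric, results_a[0].scenario, results_b[0].scenario,
                a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1),
                res.statistic, res.pvalue,
            )
        out.append(cmp_)
    return out


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the full synthetic-cohort experiment."""

    n_patients: int = 10
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    grid_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    gtv_volumes_cm3: tuple[float, ...] | None = REFERENCE_GTV_CM3
    prescriptions_gy: tuple[float, ...] | None = REFERENCE_PRESCRIPTION_GY
    regression: RegressionParams = RegressionParams()
    setup_sd_mm: float = 1.5
    falloff: FalloffModel = FalloffModel()
    adaptation_interval: int = 5
    adapt: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        simple = {
            "n_patients", "setup_sd_mm", "adaptation_interval", "adapt", "seed",
        }
        for key in simple & raw.keys():
            kwargs[key] = raw[key]
        if "grid" in raw:
            g = raw["grid"]
            kwargs["grid_shape"] = tuple(g.get("shape", (64, 64, 64)))
            kwargs["grid_spacing_mm"] = tuple(g.get("spacing_mm", (4.0,) * 3))
        if "gtv_volumes_cm3" in raw:
            v = raw["gtv_volumes_cm3"]
            kwargs["gtv_volumes_cm3"] = tuple(v) if v is not None else None
        if "prescriptions_gy" in raw:
            v = raw["prescriptions_gy"]
            kwargs["prescriptions_gy"] = tuple(v) if v is not None else None
        if "regression" in raw:
            r = dict(raw["regression"])
            if "weekly_profile" in r and r["weekly_profile"] is not None:
                r["weekly_profile"] = tuple(r["weekly_profile"])
            if "prestart_growth_range" in r:
                r["prestart_growth_range"] = tuple(r["prestart_growth_range"])
            kwargs["regression"] = RegressionParams(**r)
        if "falloff" in raw:
            kwargs["falloff"] = FalloffModel(**raw["falloff"])
        return cls(**kwargs)


@dataclass
class CohortReport:
    """All outputs of one experiment run."""

    config: ExperimentConfig
    patients: pd.DataFrame  # per-patient anatomy/course summary
    metrics: pd.DataFrame  # tidy: patient, scenario, structure, metric, value
    comparisons: pd.DataFrame  # pairwise cohort statistics

    def summary_table(self) -> pd.DataFrame:
        """Cohort mean ± sd per scenario × structure × metric."""
        g = self.metrics.groupby(["scenario", "structure", "metric"])["value"]
        out = g.agg(["mean", "std"]).reset_index()
        return out.rename(columns={"std": "sd"})

    def scenario_means(self, key: str) -> dict[str, float]:
        """Cohort mean of one ``structure/metric`` key per scenario."""
        structure, metric = key.split("/", 1)
        sel = self.metrics[
            (self.metrics.structure == structure)
            & (self.metrics.metric == metric)
        ]
        return sel.groupby("scenario")["value"].mean().to_dict()

    def comparison(self, metric: str, a: str, b: str) -> pd.Series:
        sel = self.comparisons[
            (self.comparisons.metric == metric)
            & (self.comparisons.scenario_a == a)
            & (self.comparisons.scenario_b == b)
        ]
        if sel.empty:
            raise KeyError(f"no comparison {a} vs {b} for {metric}")
        return sel.iloc[0]

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "patients.csv", index=False)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.summary_table().to_csv(out / "cohort_summary.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)


def _cohort_parameters(config: ExperimentConfig, rng: np.random.Generator):
    vols = config.gtv_volumes_cm3
    rx = config.prescriptions_gy
    if vols is None or len(vols) != config.n_patients:
        vols = tuple(
            float(np.exp(rng.uniform(np.log(100.0), np.log(500.0))))
            for _ in range(config.n_patients)
        )
    if rx is None or len(rx) != config.n_patients:
        rx = tuple(float(rng.choice([60.0, 66.0]))
                   for _ in range(config.n_patients))
    return vols, rx


def simulate_cohort(config: ExperimentConfig) -> list[tuple[str, Course]]:
    """Generate the per-patient courses for an experiment configuration."""
    master = np.random.SeedSequence(config.seed)
    param_rng = np.random.default_rng(master.spawn(1)[0])
    vols, rx = _cohort_parameters(config, param_rng)
    grid = GridSpec.centered(config.grid_shape, config.grid_spacing_mm)
    patient_seeds = master.spawn(config.n_patients + 1)[1:]
    courses = []
    for i in range(config.n_patients):
        spec = PhantomSpec(gtv_volume_cm3=vols[i])
        planning = build_phantom(spec, grid)
        course = simulate_course(
            planning, config.regression, config.setup_sd_mm, rx[i],
            patient_seeds[i], adaptation_interval=config.adaptation_interval,
        )
        courses.append((f"p{i + 1:02d}", course))
    return courses


def run_experiment(config: ExperimentConfig) -> CohortReport:
    """Run the full three-arm experiment and assemble the cohort report."""
    courses = simulate_cohort(config)
    rows, patient_rows = [], []
    results: dict[str, list[ScenarioResult]] = {s: [] for s in SCENARIOS}
    for pid, course in courses:
        obj = _objectives_for(course)
        sched = (AdaptationSchedule.weekly(course.n_fractions,
                                           config.adaptation_interval)
                 if config.adapt else
                 AdaptationSchedule.none(course.n_fractions))
        try:
            arm_results = [
                run_pplan(course, obj, config.falloff, pid),
                run_dplan(course, obj, config.falloff, pid),
                run_aplan(course, obj, sched, config.falloff, pid),
            ]
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"patient {pid}: scenario stage failed") from exc
        for res in arm_results:
            results[res.scenario].append(res)
            rows.extend(res.to_rows())
        v_plan = mask_volume(course.planning["GTV"])
        v_first = mask_volume(course.fractions[0].structures["GTV"])
        v_final = mask_volume(course.fractions[-1].structures["GTV"])
        patient_rows.append(
            {
                "patient": pid,
                "prescription_gy": course.prescription_total_gy,
                "n_fractions": course.n_fractions,
                "gtv_planning_cm3": v_plan,
                "gtv_first_fraction_cm3": v_first,
                "gtv_final_cm3": v_final,
                "gtv_residual_pct": 100.0 * v_final / v_plan,
                "ptv_planning_cm3": mask_volume(course.planning["PTV"]),
                "ptv_final_cm3": mask_volume(
                    course.fractions[-1].structures["PTV"]
                ),
            }
        )

    comp_rows = []
    for a, b in (("pPlan", "dPlan"), ("dPlan", "aPlan"), ("pPlan", "aPlan")):
        for cmp_ in compare_cohort(results[a], results[b]):
            comp_rows.append(vars(cmp_))
    return CohortReport(
        config=config,
        patients=pd.DataFrame(patient_rows),
        metrics=pd.DataFrame(rows),
        comparisons=pd.DataFrame(comp_rows),
    )
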