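"""End-to-end assessment: run every estimator family on every sampling
scheme of one dataset and emit comparison tables.

The assessment mirrors the design of single-sample-method performance
studies on managed populations: estimate Ne for (1) discrete filial
generations, (2) yearly birth cohorts and (3) sliding multi-year
cohorts, with the LD estimates demographically adjusted by Nb/Ne and
the temporal estimates by C/G, so that like is compared with like.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .coancestry import ne_m_estimate
from .demography import (
    LifeTable,
    adjust_ld,
    adjust_temporal,
    agene_nb_ne,
    factor_c,
    load_life_table,
)
from .genealogical import genealogical_ne
from .genepop import read_genepop
from .ld import LdEstimationError, ld_ne
from .pedigree import (
    Pedigree,
    SamplingScheme,
    compute_kinship,
    equivalent_generations,
    group_cohorts,
    load_pedigree,
)
from .simulate import SimulationConfig, sample_and_export, simulate_population
from .temporal import temporal_ne

log = logging.getLogger("ne_workbench")

__all__ = ["AssessmentConfig", "AssessmentResult", "run_assessment", "render_report"]


class ConfigError(ValueError):
    """Invalid or incomplete assessment configuration."""


@dataclass
class AssessmentConfig:
    pedigree_path: str | None = None
    genepop_path: str | None = None
    life_table_path: str | None = None
    simulation: SimulationConfig | None = None
    schemes: tuple[str, ...] = ("discrete", "yearly", "biannual")
    pcrits: tuple[float, ...] = (0.05, 0.02, 0.01)
    report_pcrit: float = 0.05
    adjust: bool = True
    generation_interval: float | None = None  # override G for C/G
    census_override: dict[str, float] = field(default_factory=dict)
    temporal_spans: tuple[int, ...] = (1, 3)
    max_parent_age: int = 5
    outdir: str | None = None
    seed: int | None = None

    @classmethod
    def from_file(cls, path) -> "AssessmentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("schemes", "pcrits", "temporal_spans"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)

    def validate(self) -> None:
        if self.simulation is None and (
            self.pedigree_path is None or self.genepop_path is None
        ):
            raise ConfigError(
                "either a simulation block or both pedigree and genepop paths "
                "are required")
        for p in self.pcrits:
            if not 0.0 <= p < 0.5:
                raise ConfigError(f"pcrit {p} outside [0, 0.5)")
        if not self.schemes:
            raise ConfigError("at least one sampling scheme is required")
        for path in (self.pedigree_path, self.genepop_path, self.life_table_path):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")


_SCHEME_MAP = {
    "discrete": SamplingScheme(kind="discrete_generation"),
    "yearly": SamplingScheme(kind="yearly"),
    "biannual": SamplingScheme(kind="span", span_years=2),
    "triennial": SamplingScheme(kind="span", span_years=3),
}


@dataclass
class AssessmentResult:
    single_sample: pd.DataFrame  # one row per scheme cohort
    temporal: pd.DataFrame  # one row per cohort pair
    demography: dict
    flags: list[str] = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.single_sample.to_csv(
            outdir / "single_sample_estimates.tsv", sep="\t", index=False
        )
        self.temporal.to_csv(
            outdir / "temporal_estimates.tsv", sep="\t", index=False
        )
        (outdir / "demography.json").write_text(
            json.dumps(self.demography, indent=2)
        )
        (outdir / "report.md").write_text(render_report(self))


def _registered_census(ped: Pedigree, year: int, max_age: int) -> int:
    """Living registered individuals in ``year``: born within the last
    ``max_age`` years (the pedigree has no death records, so the
    parental age cap bounds lifespan)."""
    return sum(
        1
        for ind in ped
        if ind.birth_year is not None and year - max_age < ind.birth_year <= year
    )


def run_assessment(cfg: AssessmentConfig) -> AssessmentResult:
    cfg.validate()
    flags: list[str] = []

    life_table: LifeTable | None = None
    if cfg.simulation is not None:
        sim_cfg = cfg.simulation
        if cfg.seed is not None and sim_cfg.seed is None:
            sim_cfg = dataclasses.replace(sim_cfg, seed=cfg.seed)
        sim = simulate_population(sim_cfg)
        ped = sim.pedigree
        geno, _ = sample_and_export(
            sim,
            SamplingScheme(kind="yearly"),
            typing_fraction=sim_cfg.typing_fraction,
            seed=(sim_cfg.seed or 0) + 1,
        )
        life_table = sim_cfg.life_table
    else:
        ped = load_pedigree(cfg.pedigree_path)
        geno = read_genepop(cfg.genepop_path)
        unknown = [i for i in geno.ids if i not in ped]
        if unknown:
            raise ConfigError(
                f"{len(unknown)} genotyped ids missing from the pedigree "
                f"(first: {unknown[:3]})")
    if cfg.life_table_path is not None:
        life_table = load_life_table(cfg.life_table_path)

    demo: dict = {}
    ratio = None
    c_over_g = None
    if life_table is not None:
        summary = agene_nb_ne(life_table)
        c_val, model_g = factor_c(life_table)
        g_used = cfg.generation_interval or model_g
        ratio = summary.ratio
        c_over_g = c_val / g_used
        demo = {
            "ne_dem": summary.ne_dem,
            "nb_dem": summary.nb_dem,
            "ratio_nb_ne": ratio,
            "generation_length": summary.generation_length,
            "factor_c": c_val,
            "model_g": model_g,
            "g_used": g_used,
            "c_over_g": c_over_g,
        }
    elif cfg.adjust:
        flags.append("no life table: demographic adjustments skipped")

    kin = compute_kinship(ped)
    tvec = equivalent_generations(ped)
    genotyped = set(geno.ids)

    rows = []
    for scheme_name in cfg.schemes:
        if scheme_name not in _SCHEME_MAP:
            raise ConfigError(f"unknown scheme {scheme_name!r}")
        scheme = _SCHEME_MAP[scheme_name]
        cohorts = group_cohorts(ped, scheme)
        for label, members in cohorts.items():
            typed = [i for i in members if i in genotyped]
            row: dict = {
                "scheme": scheme_name,
                "cohort": label,
                "n_registered": len(members),
                "n_typed": len(typed),
            }
            gen = None
            if len(members) >= 2:
                try:
                    gen = genealogical_ne(
                        ped, members, cohort=str(label), kinship=kin,
                        equiv_gen=tvec,
                    )
                except ValueError as exc:
                    flags.append(f"{scheme_name}/{label}: {exc}")
            if gen is not None:
                row.update(
                    mean_F=gen.mean_F,
                    mean_t=gen.mean_t,
                    mean_delta_F=gen.mean_delta_F,
                    ne_fi=gen.ne_fi,
                    se_ne_fi=gen.se_ne_fi,
                    ne_cij=gen.ne_cij,
                    se_ne_cij=gen.se_ne_cij,
                    ratio_cij_fi=gen.ratio,
                )
            if len(typed) >= 5:
                sub = geno.subset(ids=typed)
                for pcrit in cfg.pcrits:
                    try:
                        est = ld_ne(sub, pcrit=pcrit)
                    except LdEstimationError as exc:
                        flags.append(f"{scheme_name}/{label} pcrit {pcrit}: {exc}")
                        continue
                    tag = f"{pcrit:g}"
                    row[f"r2_p{tag}"] = est.mean_r2
                    row[f"ne_ld_p{tag}"] = est.point
                    row[f"ne_ld_p{tag}_lo"] = est.ci_low
                    row[f"ne_ld_p{tag}_hi"] = est.ci_high
                    if est.infinite:
                        flags.append(
                            f"{scheme_name}/{label} pcrit {pcrit}: infinite Ne(LD)")
                    if cfg.adjust and ratio is not None and scheme_name != "discrete":
                        row[f"ne_ld_p{tag}_adj"] = adjust_ld(est.point, ratio)
                nem = ne_m_estimate(sub)
                row.update(
                    fhat=nem.fhat,
                    ne_m=nem.point,
                    ne_m_lo=nem.ci_low,
                    ne_m_hi=nem.ci_high,
                )
                if nem.infinite:
                    flags.append(f"{scheme_name}/{label}: infinite Ne(M)")
            rows.append(row)
    single = pd.DataFrame(rows)

    trows = []
    yearly = group_cohorts(ped, _SCHEME_MAP["yearly"])
    ylabels = sorted(yearly, key=int)
    for span in cfg.temporal_spans:
        for i, y0 in enumerate(ylabels):
            if i + span >= len(ylabels):
                continue
            y1 = ylabels[i + span]
            if int(y1) - int(y0) != span:
                continue  # gap in the cohort series
            typed0 = [i_ for i_ in yearly[y0] if i_ in genotyped]
            typed1 = [i_ for i_ in yearly[y1] if i_ in genotyped]
            if len(typed0) < 5 or len(typed1) < 5:
                continue
            census = cfg.census_override.get(
                str(y0), _registered_census(ped, int(y0), cfg.max_parent_age)
            )
            census = max(census, len(typed0), len(typed1))
            est = temporal_ne(
                geno.subset(ids=typed0),
                geno.subset(ids=typed1),
                census=census,
                elapsed_years=span,
            )
            trow = {
                "from": y0,
                "to": y1,
                "span_years": span,
                "n_x": len(typed0),
                "n_y": len(typed1),
                "census": census,
                "fs": est.fs,
                "fs_prime": est.fs_prime,
                "ne_jr": est.point,
                "ci_lo": est.ci_low,
                "ci_hi": est.ci_high,
            }
            if est.infinite:
                flags.append(f"temporal {y0}->{y1}: infinite Ne(JR)")
            if cfg.adjust and c_over_g is not None:
                trow["ne_jr_adj"] = adjust_temporal(est.point, c_over_g, 1.0)
            trows.append(trow)
    temporal = pd.DataFrame(trows)

    result = AssessmentResult(
        single_sample=single, temporal=temporal, demography=demo, flags=flags
    )
    if cfg.outdir is not None:
        result.write(cfg.outdir)
    return result


def _fmt(v, digits=3) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    if isinstance(v, float):
        if math.isinf(v):
            return "inf"
        return f"{v:.{digits}g}"
    return str(v)


def render_report(result: AssessmentResult) -> str:
    """Human-readable markdown summary of an assessment bundle."""
    parts: list[str] = ["# Effective-size assessment\n"]
    if result.demography:
        d = result.demography
        parts.append("## Demographic model\n")
        parts.append(
            f"- Ne (per generation): {_fmt(d['ne_dem'], 4)}\n"
            f"- Nb (single cohort): {_fmt(d['nb_dem'], 4)}\n"
            f"- Nb/Ne ratio: {_fmt(d['ratio_nb_ne'])}\n"
            f"- generation length T: {_fmt(d['generation_length'])}\n"
            f"- factor C: {_fmt(d['factor_c'])} (model G {_fmt(d['model_g'])}, "
            f"G used {_fmt(d['g_used'])}, C/G {_fmt(d['c_over_g'])})\n"
        )
    if not result.single_sample.empty:
        parts.append("\n## Single-sample estimates\n")
        parts.append(_markdown_table(result.single_sample))
    if not result.temporal.empty:
        parts.append("\n## Temporal (two-sample) estimates\n")
        parts.append(_markdown_table(result.temporal))
    if result.flags:
        parts.append("\n## Flags\n")
        parts.extend(f"- {f}\n" for f in result.flags)
    return "".join(parts)


def _markdown_table(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append(
            "| " + " | ".join(_fmt(row[c]) for c in cols) + " |"
        )
    return "\n".join(lines) + "\n"
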