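"""One-command reproduction of the full scat-diet analysis.

Orchestrates, from input CSVs: occurrence tabulation, per-group Levin's
niche breadth with bootstrap intervals, Mao Tau accumulation curves,
fractional trophic level, and the stable-isotope summary (group variances,
Levene tests, two-factor ANOVA on delta-15N, Bonferroni pairwise t-tests).
Stages whose inputs are absent are skipped with a logged warning; if no
stage can run at all that is an error.

Group-comparison scheme (config-driven, defaulting to the study design):
years collapse into two eras — early (two years after the invasion) and
late (seven years after) — and contrasts run within-river across eras for
rivers sampled in both, plus across rivers within the late era.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .accumulation import accumulation_ci
from .isotope_stats import anova_two_factor, normality_check, pairwise_t_bonferroni, variance_niche
from .niche_breadth import group_niche_breadth
from .scat_data import (
    PreyReference,
    SchemaError,
    filter_prey_by_length,
    incidence_matrix,
    read_isotopes,
    read_scats,
    tabulate_occurrences,
)
from .trophic import group_ftl

__all__ = ["AnalysisConfig", "PipelineError", "ReportBundle", "run_full_analysis", "load_config"]

log = logging.getLogger("scatniche")


class PipelineError(RuntimeError):
    """No analysis stage could be executed."""


@dataclass
class AnalysisConfig:
    scats_path: str | None = None
    isotopes_path: str | None = None
    prey_reference_path: str | None = None  # None -> packaged reference
    output_dir: str = "scatniche_out"
    n_boot: int = 1000
    seed: int = 17
    levene_center: str = "mean"
    equal_var_policy: str = "auto"
    min_prey_length_mm: float = 100.0
    early_years: tuple[int, ...] = (2009, 2010)

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a flat key-value YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a flat mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if "early_years" in raw:
        raw["early_years"] = tuple(int(y) for y in raw["early_years"])
    return AnalysisConfig(**raw)


@dataclass
class ReportBundle:
    occurrence: pd.DataFrame | None = None
    niche: pd.DataFrame | None = None
    accumulation: pd.DataFrame | None = None
    ftl: pd.DataFrame | None = None
    isotope_groups: pd.DataFrame | None = None
    isotope_levene: pd.DataFrame | None = None
    isotope_anova: pd.DataFrame | None = None
    isotope_pairwise: pd.DataFrame | None = None
    written: list[Path] = field(default_factory=list)


def _era(year: int, early_years: tuple[int, ...]) -> str:
    return "early" if year in early_years else "late"


def _write(df: pd.DataFrame, out_dir: Path, name: str, bundle: ReportBundle) -> None:
    path = out_dir / name
    df.to_csv(path, index=False)
    bundle.written.append(path)
    log.info("wrote %s (%d rows)", path, len(df))


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run every stage the config's inputs allow and write the result tables."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()
    ran_any = False

    collection = None
    if config.scats_path:
        collection = read_scats(config.scats_path)
        log.info("read %d scats from %s", len(collection), config.scats_path)

    if collection is not None:
        occ = tabulate_occurrences(collection)
        bundle.occurrence = occ.to_display().merge(
            occ.per_group, on=["river", "year"], how="left"
        )
        _write(bundle.occurrence, out_dir, "occurrence.csv", bundle)

        bundle.niche = group_niche_breadth(
            collection, n_boot=config.n_boot, seed=config.seed
        )
        _write(bundle.niche, out_dir, "niche.csv", bundle)

        acc_rows = []
        for river, year in collection.groups():
            recs = collection.group_records(river, year)
            inc = incidence_matrix(recs)
            if inc.shape[1] == 0:
                log.warning("group (%s, %s) has no prey records; accumulation skipped", river, year)
                continue
            curve = accumulation_ci(inc, n_boot=config.n_boot, seed=config.seed)
            for h in range(1, curve.H + 1):
                acc_rows.append(
                    (river, year, h, curve.tau[h - 1], curve.ci_low[h - 1], curve.ci_high[h - 1])
                )
        bundle.accumulation = pd.DataFrame(
            acc_rows, columns=["river", "year", "h", "tau", "ci_low", "ci_high"]
        )
        _write(bundle.accumulation, out_dir, "accumulation.csv", bundle)

        reference = (
            PreyReference.from_csv(config.prey_reference_path)
            if config.prey_reference_path
            else _packaged_reference()
        )
        reference = filter_prey_by_length(reference, config.min_prey_length_mm)
        try:
            bundle.ftl = group_ftl(
                collection, reference, n_boot=config.n_boot, seed=config.seed
            )
            _write(bundle.ftl, out_dir, "ftl.csv", bundle)
        except ValueError as exc:
            log.warning("trophic-level stage skipped: %s", exc)
        ran_any = True
    else:
        log.warning("no scats_path configured; GSA stages skipped")

    if config.isotopes_path:
        iso = read_isotopes(config.isotopes_path)
        if collection is not None:
            contaminated = {r.scat_id for r in collection if r.contaminated}
            n_drop = int(iso["scat_id"].isin(contaminated).sum())
            if n_drop:
                log.warning("dropping %d isotope sample(s) from contaminated scats", n_drop)
                iso = iso[~iso["scat_id"].isin(contaminated)]
        counts = iso.groupby(["river", "year"]).size()
        usable = counts[counts >= 2]
        small = counts[counts < 2]
        for (river, year), n in small.items():
            log.warning("isotope group (%s, %s) has n=%d < 2; excluded", river, year, n)
        iso = iso.merge(
            usable.rename("n").reset_index()[["river", "year"]], on=["river", "year"]
        )
        if len(usable) >= 2:
            frames = []
            for isotope in ("d15N", "d13C"):
                summary = variance_niche(iso, isotope=isotope, center=config.levene_center)
                g = summary.per_group.copy()
                g.insert(0, "isotope", isotope)
                frames.append(g)
                lev_rows = [
                    (isotope, " | ".join(summary.omnibus.groups), "omnibus",
                     summary.omnibus.statistic, summary.omnibus.pvalue)
                ] + [
                    (isotope, f"{r.groups[0]} vs {r.groups[1]}", "pairwise", r.statistic, r.pvalue)
                    for r in summary.pairwise
                ]
                lev = pd.DataFrame(
                    lev_rows, columns=["isotope", "contrast", "kind", "W", "p"]
                )
                bundle.isotope_levene = (
                    lev if bundle.isotope_levene is None
                    else pd.concat([bundle.isotope_levene, lev], ignore_index=True)
                )
            bundle.isotope_groups = pd.concat(frames, ignore_index=True)
            _write(bundle.isotope_groups, out_dir, "isotope_groups.csv", bundle)
            _write(bundle.isotope_levene, out_dir, "isotope_levene.csv", bundle)

            for isotope in ("d15N",):
                check = normality_check(iso[isotope])
                log.info("normality of %s: %s (W=%.3f, p=%.3f)", isotope, check.verdict,
                         check.statistic, check.pvalue)

            iso = iso.assign(era=[_era(int(y), config.early_years) for y in iso["year"]])
            anova_sub = iso[iso.groupby("river")["era"].transform("nunique") == 2]
            if anova_sub["river"].nunique() >= 2:
                res = anova_two_factor(
                    anova_sub["d15N"], anova_sub["river"], anova_sub["era"].factorize()[0],
                    log_transform=True,
                )
                tab = res.table.reset_index(names="term")
                bundle.isotope_anova = tab
                _write(tab, out_dir, "isotope_anova.csv", bundle)
            else:
                log.warning("fewer than two rivers sampled in both eras; ANOVA skipped")

            labels = iso["river"].str.cat(iso["era"], sep=" ")
            present = set(labels)
            contrasts = []
            rivers = sorted(iso["river"].unique())
            eras = sorted(iso["era"].unique())
            for river in rivers:  # within river, across eras
                pair = [f"{river} {e}" for e in eras]
                if len(eras) == 2 and all(x in present for x in pair):
                    contrasts.append(tuple(pair))
            for i, r1 in enumerate(rivers):  # across rivers, within era
                for r2 in rivers[i + 1:]:
                    for e in eras:
                        pair = (f"{r1} {e}", f"{r2} {e}")
                        if all(x in present for x in pair):
                            contrasts.append(pair)
            if contrasts:
                bundle.isotope_pairwise = pairwise_t_bonferroni(
                    iso["d15N"], labels, contrasts, equal_var_policy=config.equal_var_policy
                )
                _write(bundle.isotope_pairwise, out_dir, "isotope_pairwise.csv", bundle)
            ran_any = True
        else:
            log.warning("fewer than two isotope groups with n >= 2; SIA skipped")
    else:
        log.warning("no isotopes_path configured; SIA stage skipped")

    if not ran_any:
        raise PipelineError("no analysis stage could be executed with this config")

    run_log = out_dir / "run_log.txt"
    with open(run_log, "w", encoding="utf-8") as fh:
        fh.write(f"scatniche {__version__}\n")
        for key, value in vars(config).items():
            fh.write(f"{key} = {value}\n")
        for path in bundle.written:
            fh.write(f"output: {path.name}\n")
    bundle.written.append(run_log)
    return bundle


def _packaged_reference() -> PreyReference:
    from .synthetic_data import packaged_prey_reference

    return packaged_prey_reference()
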