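"""End-to-end report generation: carrier tables, concordance reports, power curves.

Thin orchestration over the counting, estimation, testing and power modules;
every run emits a provenance record (panel name/version, QC settings, seed)
so outputs are traceable to their inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .carrier import estimate_carrier, format_one_in
from .concordance import batch_concordance, gof_test_range
from .counts import (
    QcConfig,
    SampleManifest,
    SiteObservation,
    count_alleles,
    observations_from_table,
    pool_observations,
)
from .panel import DiseasePanel, load_panel
from .power import detection_curve

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and options for an end-to-end run."""

    panel_path: Optional[Path] = None
    vcf_paths: list[Path] = field(default_factory=list)
    manifest_paths: list[Path] = field(default_factory=list)
    observations_path: Optional[Path] = None
    reference_path: Optional[Path] = None
    out_dir: Path = Path(".")
    qc: QcConfig = field(default_factory=QcConfig)
    continuity: bool = True
    alpha: float = 0.05
    sigma_grid: tuple[float, ...] = (0.0, 0.01, 0.1)
    power_p: float = 0.001
    n_min: int = 1
    n_max: int = 100_000
    n_points: int = 100
    seed: int = 0


def provenance(config: RunConfig, panel: Optional[DiseasePanel] = None) -> dict:
    return {
        "package_version": __version__,
        "panel": panel.name if panel else None,
        "panel_version": panel.version if panel else None,
        "qc": dataclasses.asdict(config.qc),
        "continuity": config.continuity,
        "alpha": config.alpha,
        "seed": config.seed,
    }


def gather_observations(config: RunConfig, panel: DiseasePanel) -> list[SiteObservation]:
    """Observations from a printed table and/or VCF+manifest pairs."""
    obs: list[SiteObservation] = []
    if config.observations_path is not None:
        obs += observations_from_table(config.observations_path, panel)
    for vcf_path, manifest_path in zip(config.vcf_paths, config.manifest_paths):
        manifest = SampleManifest.from_tsv(manifest_path)
        obs += count_alleles(vcf_path, manifest, panel, qc=config.qc)
    return obs


def carrier_table(
    observations: Sequence[SiteObservation],
    superpop: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-(mutation × population) carrier matrix, with pooled superpopulation rows.

    Columns mirror the published layout: af, ac, an, one_in, plus the
    rare-allele validity flag.  When a population → superpopulation mapping
    is given, pooled rows (cohort label "POOLED") are appended per
    superpopulation.
    """
    rows = []

    def add(obs: SiteObservation) -> None:
        est = estimate_carrier(obs)
        rec = obs.record
        rows.append(
            {
                "mutation_key": obs.mutation_key,
                "disease": rec.disease_name if rec else "",
                "gene": rec.gene_symbol if rec else "",
                "population": obs.population,
                "cohort": obs.cohort,
                "ac": obs.ac,
                "an": obs.an,
                "af": est.af,
                "carrier_rate": est.carrier_rate,
                "het_frequency": est.het_frequency,
                "one_in": format_one_in(est.one_in),
                "hwe_valid": est.hwe_valid,
            }
        )

    for obs in observations:
        add(obs)
    if superpop:
        by_group: dict[tuple[str, str], list[SiteObservation]] = {}
        for obs in observations:
            sp = superpop.get(obs.population)
            if sp is None or sp == obs.population:
                continue
            by_group.setdefault((obs.mutation_key, sp), []).append(obs)
        for (mkey, sp), group in sorted(by_group.items()):
            add(pool_observations(group, population=sp, cohort="POOLED"))
    return pd.DataFrame(rows)


def run_carrier_analysis(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Produce the carrier table and its provenance record."""
    if config.panel_path is None:
        raise ValueError("carrier analysis needs a panel")
    panel = load_panel(config.panel_path)
    obs = gather_observations(config, panel)
    if not obs:
        raise ValueError("no observations: no panel mutation found in the inputs")
    table = carrier_table(obs)
    prov = provenance(config, panel)
    prov["n_observations"] = len(obs)
    prov["n_mutations"] = table["mutation_key"].nunique()
    prov["n_diseases"] = int(table.loc[table["ac"] > 0, "disease"].nunique())
    return table, prov


def load_reference_table(path: str | Path) -> pd.DataFrame:
    """Reference-prevalence TSV: population, expected_af_low, expected_af_high, source."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "expected_af_low", "expected_af_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: reference table missing columns {sorted(missing)}")
    return df


def prevalence_concordance(
    observations: Sequence[SiteObservation],
    reference: pd.DataFrame,
    mutation_key: str,
) -> pd.DataFrame:
    """Goodness-of-fit of one mutation's per-population AFs against literature AFs.

    Reference ranges yield a p-value interval (both endpoints evaluated);
    exact 0-vs-0 agreements are reported as such (no statistic).
    """
    by_pop = {
        o.population: o for o in observations if o.mutation_key == mutation_key
    }
    rows = []
    for ref_row in reference.itertuples():
        obs = by_pop.get(ref_row.population)
        if obs is None:
            continue
        lo_res, hi_res = gof_test_range(
            obs.ac, obs.an, float(ref_row.expected_af_low), float(ref_row.expected_af_high)
        )
        exact = lo_res.exact_agreement and hi_res.exact_agreement
        rows.append(
            {
                "mutation_key": mutation_key,
                "population": ref_row.population,
                "ac": obs.ac,
                "an": obs.an,
                "observed_af": obs.af,
                "expected_af_low": ref_row.expected_af_low,
                "expected_af_high": ref_row.expected_af_high,
                "chi2_low": lo_res.chi2,
                "chi2_high": hi_res.chi2,
                "p_low": min(lo_res.p_value, hi_res.p_value),
                "p_high": max(lo_res.p_value, hi_res.p_value),
                "exact_agreement": exact,
            }
        )
    return pd.DataFrame(rows)


def run_concordance_report(
    config: RunConfig,
    observations: Sequence[SiteObservation],
    pairing: Optional[Sequence[tuple[str, str]]] = None,
    reference_mutation: Optional[str] = None,
) -> dict[str, pd.DataFrame]:
    """Cohort-vs-cohort batch tests plus optional literature-prevalence tests."""
    out: dict[str, pd.DataFrame] = {}
    cohorts = sorted({o.cohort for o in observations} - {"POOLED"})
    if len(cohorts) == 2:
        a = [o for o in observations if o.cohort == cohorts[0]]
        b = [o for o in observations if o.cohort == cohorts[1]]
        out["cohort_pairwise"] = batch_concordance(
            a, b, pairing=pairing, continuity=config.continuity, alpha=config.alpha
        )
    if config.reference_path is not None and reference_mutation is not None:
        reference = load_reference_table(config.reference_path)
        out["prevalence"] = prevalence_concordance(
            observations, reference, reference_mutation
        )
    return out


def run_power_report(config: RunConfig) -> pd.DataFrame:
    """Long-format detection-power table over the configured sigma grid."""
    rows = []
    for sigma in config.sigma_grid:
        curve = detection_curve(
            config.power_p, sigma, config.n_min, config.n_max, config.n_points
        )
        for n, d in curve.points:
            rows.append({"p": config.power_p, "sigma": sigma, "n": n, "detection": d})
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_provenance(prov: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(prov, indent=1, default=str) + "\n")
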