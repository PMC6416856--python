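"""End-to-end orchestration of all analysis stages with a run manifest.

Each stage consumes one input table and is independent of the others except
for the shared :class:`~wormlife.config.Config`; a stage whose input file is
absent is skipped and marked in the manifest rather than failing the run.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import demography, fecundity, io, milestones, phenotypes, survival
from .config import Config

logger = logging.getLogger(__name__)

INPUT_PATTERNS = {
    "milestone": ("*ilestone*.tsv",),
    "lifespan": ("*ifespan*.tsv",),
    "fecundity": ("*ecundity*.tsv",),
    "viability": ("*iability*.tsv",),
    "lifetable": ("*ife_table*.tsv", "*ifetable*.tsv"),
    "simplemine": ("*implemine*.tsv", "*implemine*.txt"),
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str
    input_checksums: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _find_input(input_dir: Path, schema: str) -> Path | None:
    for pattern in INPUT_PATTERNS[schema]:
        hits = sorted(input_dir.glob(pattern))
        if hits:
            return hits[0]
    return None


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format="%.6g")


def run_all(
    config: Config,
    input_dir: str | Path,
    out_dir: str | Path,
    stages: list[str] | None = None,
) -> RunManifest:
    """Run every requested stage whose input table exists.

    Outputs one TSV per summary plus ``manifest.json``; every stochastic
    stage is seeded from ``config.random_seed``, so a rerun with identical
    inputs and config reproduces the outputs byte for byte.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            "random_seed": config.random_seed,
            "bootstrap_reps": config.bootstrap_reps,
            "adult_offset_days": dict(config.adult_offset_days),
            "offspring_scaling": config.offspring_scaling,
            "ci_level": config.ci_level,
        },
        seed=config.random_seed,
        package_version=__version__,
    )

    requested = stages or ["milestones", "lifespan", "fecundity", "demography",
                           "viability", "phenotypes"]

    inputs: dict[str, Path | None] = {
        schema: _find_input(input_dir, schema) for schema in INPUT_PATTERNS
    }
    for schema, path in inputs.items():
        if path is not None:
            manifest.input_checksums[path.name] = _md5(path)

    def _skip(stage, reason):
        manifest.stages[stage] = {"status": "skipped", "reason": reason}
        logger.info("stage %s skipped: %s", stage, reason)

    # --- milestones -------------------------------------------------------
    if "milestones" in requested:
        if inputs["milestone"] is None:
            _skip("milestones", "no milestone input table")
        else:
            ds = io.read_table(inputs["milestone"], "milestone")
            table = milestones.median_milestone_table(ds.df, config.ci_level)
            _write(table, out_dir / "milestone_medians.tsv")
            lrt_rows = []
            for (temp, mile), sub in ds.df.groupby(["temperature", "milestone"]):
                for sp_a, sp_b in itertools.combinations(
                    sorted(sub["species"].unique()), 2
                ):
                    try:
                        res = milestones.compare_species_lrt(
                            sub[sub["species"] == sp_a],
                            sub[sub["species"] == sp_b],
                        )
                        lrt_rows.append(
                            dict(temperature=temp, milestone=mile,
                                 species_a=sp_a, species_b=sp_b,
                                 chisq=res.chisq, df=res.df, p_value=res.p_value)
                        )
                    except milestones.DegenerateDataError as exc:
                        lrt_rows.append(
                            dict(temperature=temp, milestone=mile,
                                 species_a=sp_a, species_b=sp_b,
                                 chisq=float("nan"), df=2,
                                 p_value=float("nan"), note=str(exc))
                        )
            if lrt_rows:
                _write(pd.DataFrame(lrt_rows), out_dir / "milestone_lrt.tsv")
            manifest.stages["milestones"] = {"status": "ok",
                                             "n_groups": len(table)}

    # --- lifespan ---------------------------------------------------------
    if "lifespan" in requested:
        if inputs["lifespan"] is None:
            _skip("lifespan", "no lifespan input table")
        else:
            ds = io.read_table(inputs["lifespan"], "lifespan")
            adult = survival.adult_lifespan_transform(ds.df, config)
            rows = []
            for label, frame in [("total", ds.df), ("adult", adult)]:
                for sp, sub in frame.groupby("species"):
                    curve = survival.km_fit(sub)
                    rows.append(
                        dict(species=sp, scale=label, n=len(sub),
                             median_lifespan=survival.median_lifespan(curve))
                    )
                    curve.to_frame().to_csv(
                        out_dir / f"survivorship_{label}_{sp}.tsv",
                        sep="\t", index=False, lineterminator="\n",
                    )
            _write(pd.DataFrame(rows), out_dir / "lifespan_medians.tsv")
            ph_rows = []
            for label, frame in [("total", ds.df), ("adult", adult)]:
                for sp_a, sp_b in itertools.combinations(
                    sorted(frame["species"].unique()), 2
                ):
                    res = survival.ph_compare(
                        frame[frame["species"] == sp_a],
                        frame[frame["species"] == sp_b],
                    )
                    ph_rows.append(
                        dict(scale=label, species_a=sp_a, species_b=sp_b,
                             log_hazard_ratio=res.log_hazard_ratio,
                             std_error=res.std_error, z_value=res.z_value,
                             p_value=res.p_value,
                             monotone=res.monotone_likelihood)
                    )
            if ph_rows:
                _write(pd.DataFrame(ph_rows), out_dir / "lifespan_ph.tsv")
            manifest.stages["lifespan"] = {"status": "ok"}

    # --- fecundity --------------------------------------------------------
    if "fecundity" in requested:
        if inputs["fecundity"] is None:
            _skip("fecundity", "no fecundity input table")
        else:
            ds = io.read_table(inputs["fecundity"], "fecundity")
            summary_all = fecundity.brood_summary(ds.df, drop_failed=False)
            summary_all["drop_failed"] = False
            summary_ok = fecundity.brood_summary(ds.df, drop_failed=True)
            summary_ok["drop_failed"] = True
            _write(pd.concat([summary_all, summary_ok], ignore_index=True),
                   out_dir / "brood_summary.tsv")
            broods = fecundity.lifetime_broods(ds.df)
            test_rows = []
            keys = [c for c in ("temperature", "regime") if c in broods.columns]
            grouped = broods.groupby(keys) if keys else [((), broods)]
            for key, sub in grouped:
                if not isinstance(key, tuple):
                    key = (key,)
                for sp_a, sp_b in itertools.combinations(
                    sorted(sub["species"].unique()), 2
                ):
                    res = fecundity.rank_sum_test(
                        sub.loc[sub["species"] == sp_a, "lifetime_brood"],
                        sub.loc[sub["species"] == sp_b, "lifetime_brood"],
                    )
                    row = dict(zip(keys, key))
                    row.update(species_first=sp_a, species_second=sp_b,
                               u_first=res.u_first, u_second=res.u_second,
                               p_value=res.p_value, method=res.method)
                    test_rows.append(row)
                # failed-cross contingency per species pair
                for sp_a, sp_b in itertools.combinations(
                    sorted(sub["species"].unique()), 2
                ):
                    fa = int((sub.loc[sub["species"] == sp_a,
                                      "lifetime_brood"] == 0).sum())
                    na = int((sub["species"] == sp_a).sum())
                    fb = int((sub.loc[sub["species"] == sp_b,
                                      "lifetime_brood"] == 0).sum())
                    nb = int((sub["species"] == sp_b).sum())
                    fres = fecundity.fisher_exact([[fa, na - fa], [fb, nb - fb]])
                    row = dict(zip(keys, key))
                    row.update(test="fisher_failed_crosses",
                               species_first=sp_a, species_second=sp_b,
                               odds_ratio=fres.odds_ratio_cmle,
                               p_value=fres.p_two_sided)
                    test_rows.append(row)
            if test_rows:
                _write(pd.DataFrame(test_rows), out_dir / "fecundity_tests.tsv")
            manifest.stages["fecundity"] = {"status": "ok"}

    # --- viability --------------------------------------------------------
    if "viability" in requested:
        if inputs["viability"] is None:
            _skip("viability", "no viability input table")
        else:
            ds = io.read_table(inputs["viability"], "viability")
            _write(demography.viability_summary(ds.df),
                   out_dir / "viability_summary.tsv")
            manifest.stages["viability"] = {"status": "ok"}

    # --- demography -------------------------------------------------------
    if "demography" in requested:
        if inputs["lifetable"] is not None:
            ds = io.read_table(inputs["lifetable"], "lifetable")
            rows = []
            keys = [c for c in ("species", "regime") if c in ds.df.columns]
            grouped = ds.df.groupby(keys) if keys else [((), ds.df)]
            for key, sub in grouped:
                if not isinstance(key, tuple):
                    key = (key,)
                table = demography.LifeTable.from_frame(sub)
                row = dict(zip(keys, key))
                row.update(r=demography.euler_lotka_r(table),
                           R0=table.net_reproductive_rate, mode="direct")
                rows.append(row)
            _write(pd.DataFrame(rows), out_dir / "rate_estimates.tsv")
            manifest.stages["demography"] = {"status": "ok", "mode": "direct"}
        elif (
            inputs["lifespan"] is not None
            and inputs["fecundity"] is not None
            and inputs["viability"] is not None
        ):
            life = io.read_table(inputs["lifespan"], "lifespan").df
            fec = io.read_table(inputs["fecundity"], "fecundity").df
            via = io.read_table(inputs["viability"], "viability").df
            rows = []
            for sp in sorted(fec["species"].unique()):
                if sp not in config.adult_offset_days:
                    logger.warning("no maturation offset for %s; skipped", sp)
                    continue
                sub_life = life[life["species"] == sp]
                sub_via = via[via["species"] == sp]
                if len(sub_life) == 0 or len(sub_via) == 0:
                    continue
                temps = fec.loc[fec["species"] == sp, "temperature"]
                if "temperature" in sub_via.columns and len(temps):
                    match = sub_via[sub_via["temperature"] == temps.iloc[0]]
                    if len(match):
                        sub_via = match
                scheds = demography.schedules_from_frame(
                    fec[fec["species"] == sp]
                )
                est = demography.bootstrap_r_ci(
                    sub_life, scheds, sub_via, config,
                    maturation_day=config.adult_offset_days[sp],
                )
                rows.append(
                    dict(species=sp, r=est.r, R0=est.net_reproductive_rate,
                         ci_low=est.ci_low, ci_high=est.ci_high,
                         bootstrap_reps=est.bootstrap_reps, seed=est.seed,
                         n_failed=est.n_failed, flagged=est.flagged,
                         mode="built")
                )
            if rows:
                _write(pd.DataFrame(rows), out_dir / "rate_estimates.tsv")
                manifest.stages["demography"] = {"status": "ok", "mode": "built"}
            else:
                _skip("demography", "no species with complete inputs")
        else:
            _skip("demography", "needs a life table or all three cohort tables")

    # --- phenotypes -------------------------------------------------------
    if "phenotypes" in requested:
        if inputs["simplemine"] is None:
            _skip("phenotypes", "no simplemine export")
        else:
            matrix = phenotypes.parse_simplemine(inputs["simplemine"])
            counts = phenotypes.intersection_counts(matrix)
            rows = [
                {"subset": " & ".join(sorted(k)), "n_genes": v}
                for k, v in sorted(
                    counts.counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
                )
            ]
            rows.append({"subset": "TOTAL_WITH_ANY",
                         "n_genes": counts.total_with_any})
            rows.append({"subset": "TOTAL_GENES", "n_genes": counts.total_genes})
            rows.append({"subset": "NO_LIFE_HISTORY_PHENOTYPE",
                         "n_genes": counts.total_genes - counts.total_with_any})
            _write(pd.DataFrame(rows), out_dir / "phenotype_counts.tsv")
            phenotypes.write_upset_matrix(matrix, out_dir / "upset_matrix.tsv")
            manifest.stages["phenotypes"] = {"status": "ok"}

    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
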