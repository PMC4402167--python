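"""End-to-end pipeline: synthesize/load -> preprocess -> phenotype -> validate -> ROC.

All randomness flows from a single seed through named substreams (synth,
cluster shuffling, split), so identical configurations produce identical
report bundles.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_synth import (CohortSpec, default_spec, generate_cohort,
                           read_cohort_csv, write_cohort_csv)
from .crossval import cross_validate_phenotypes
from .phenotyping import phenotype_prevalences, run_phenotyping
from .preprocessing import apply_exclusions, derive_columns
from .roc_cutpoint import (SCENARIOS, candidate_table, report_to_json_dict,
                           stepwise_report)

logger = logging.getLogger("phenocut")

_SUBSTREAMS = {"synth": 1, "cluster": 2, "split": 3}


def substream_seed(seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the pipeline seed."""
    return int(np.random.SeedSequence([seed, _SUBSTREAMS[name]])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; exactly one input source."""

    input_csv: str | None = None
    synth_spec: CohortSpec | None = None
    n_total: int = 1902
    seed: int = 0
    split_fraction: float = 0.5
    policy: str = "youden_sens"
    scenarios: tuple = SCENARIOS
    out_dir: str | None = None
    alpha: float = 0.05
    use_synth: bool = True

    def __post_init__(self):
        if self.input_csv is not None and self.synth_spec is not None:
            raise ValueError("provide either input_csv or synth_spec, not both")
        if self.input_csv is not None:
            self.use_synth = False


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and optionally writes) the bundle."""
    t0 = time.time()
    seed = config.seed

    # 1. input
    if config.input_csv is not None:
        df = read_cohort_csv(config.input_csv)
        logger.info("stage=load n=%d file=%s", len(df), config.input_csv)
    else:
        spec = config.synth_spec or default_spec(n_total=config.n_total)
        df = generate_cohort(spec, seed=substream_seed(seed, "synth"))
        logger.info("stage=synth n=%d", len(df))

    # 2. preprocessing
    df, exclusions = apply_exclusions(df)
    df = derive_columns(df)
    logger.info("stage=preprocess n=%d excluded=%s", len(df), exclusions)

    # 3. phenotyping (per-stratum two-step clustering)
    table, stratum_results, pheno_info = run_phenotyping(
        df, seed=substream_seed(seed, "cluster"), alpha=config.alpha,
        compute_quality=True)
    logger.info("stage=phenotype n=%d underweight=%d", len(table),
                pheno_info["n_underweight_excluded"])

    # 4. cross-validation
    cv = cross_validate_phenotypes(df, fraction=config.split_fraction,
                                   seed=substream_seed(seed, "split"))
    logger.info("stage=crossval kappa=%.3f n=%d", cv["kappa"], cv["n"])

    # 5. stepwise ROC / cutpoints
    roc = stepwise_report(table, policy=config.policy)
    logger.info("stage=roc done")

    bundle = {
        "version": __version__,
        "seed": seed,
        "n_input": int(len(df)),
        "exclusions": exclusions,
        "phenotype_info": pheno_info,
        "phenotype_prevalences": {
            k: float(v) for k, v in phenotype_prevalences(table).items()},
        "strata": [r.to_dict() for r in stratum_results],
        "crossval": {
            "kappa": cv["kappa"], "z": cv["z"], "p": cv["p"], "n": cv["n"],
            "confusion": np.asarray(cv["confusion"]).tolist(),
            "categories": cv["categories"],
        },
        "roc": report_to_json_dict(roc),
        "elapsed_s": round(time.time() - t0, 3),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle_path = out / "report.json"
        bundle_path.write_text(json.dumps(bundle, indent=2, sort_keys=True))
        write_cohort_csv(table.assign(), out / "cohort_phenotyped.csv")
        table[["id", "phenotype"]].to_csv(out / "phenotypes.csv", index=False)
        pd.DataFrame(np.asarray(cv["confusion"]),
                     index=cv["categories"], columns=cv["categories"]
                     ).to_csv(out / "crossval_confusion.csv")
        cands = pd.concat([
            candidate_table(roc["genders"][g]["curves"][s])
            for g in roc["genders"] for s in SCENARIOS
        ], ignore_index=True)
        cands.to_csv(out / "cutpoint_candidates.csv", index=False)
        logger.info("stage=write out=%s", out)
    return bundle
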