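"""Shared paths and the study-shaped configuration for the analysis scripts.

The scripts form a numbered narrative: 01 simulates a study-shaped RIL
population, 02 filters SNPs, 03 builds the bin map, 04 the genetic map, 05
the trait statistics, 06 the CIM QTL scan, and 07 the map summary. Heavy
intermediate artifacts (genotype matrices, VCF, truth) live under
``scratch/analysis``; the report tables land in ``results/analysis``.
"""

from __future__ import annotations

import argparse
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results" / "analysis"


def parser(description: str) -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=RESULTS)
    return ap


def study_config(seed: int):
    """Desk-scale population shaped like the study: 200 F7 lines, 11
    chromosomes of 40 Mb (~1.3 Morgans each), ~30 SNPs per 100 Kb window,
    planted ANT/PL QTLs and one distortion region."""
    from beanqtl.simulate import default_study_config

    return default_study_config(seed=seed, snp_density=300.0)


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
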