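#!/usr/bin/env python
"""Prey electivity: is each family eaten in proportion to availability?

Jacobs' D per family, one value per survey reef (pooled DNA diet
against that reef's availability), with a 95% t-interval across reefs
and the conservative +/-0.25 neutrality band.
"""

from pathlib import Path

import pandas as pd

from trophimix import io
from trophimix.electivity import electivity_profile

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

comp = pd.read_csv(OUT / "dna_composition.csv").set_index("category")["proportion"]
surveys = pd.read_csv(ROOT / "results" / "data" / "surveys.csv")

profile = electivity_profile(comp, surveys)
io.write_csv(profile.drop(columns=["D_per_reef"]).reset_index(), OUT / "electivity.csv")
print(profile.drop(columns=["D_per_reef"]).round(3).to_string())
if profile.attrs["excluded_families"]:
    print("excluded (not surveyed):", ", ".join(profile.attrs["excluded_families"]))
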