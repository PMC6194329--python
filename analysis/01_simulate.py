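#!/usr/bin/env python
"""Generate the synthetic study: stomachs, hit tables, tissues, surveys.

One ground-truth scenario (two predator groups, six prey families, 56%
empty stomachs, 10% hit-table contamination) drives every later stage,
so each analysis can be checked against known truth. Writes all input
tables under results/data/.
"""

from pathlib import Path

from trophimix import io, synthetic

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1

scenario = synthetic.default_scenario(seed=SEED)
records = synthetic.simulate_stomachs(scenario, n_predators=120)
hits = synthetic.simulate_hit_table(records, scenario)
surveys = synthetic.simulate_surveys(scenario)

io.scenario_to_yaml(scenario, OUT / "scenario.yaml")
io.write_csv(records, OUT / "prey_records.csv")
io.write_csv(hits, OUT / "hit_table.csv")
io.write_csv(surveys, OUT / "surveys.csv")
for tissue in synthetic.TISSUES:
    cons = synthetic.simulate_consumers(scenario, tissue, n_consumers=40)
    io.write_csv(cons, OUT / f"consumers_{tissue}.csv")

n_total = len(records.attrs["stomach_ids"])
n_empty = len(records.attrs["empty_stomach_ids"])
print(f"simulated {n_total} stomachs ({n_empty} empty, "
      f"{100 * (1 - n_empty / n_total):.0f}% contained prey), "
      f"{len(records)} prey items, {len(hits)} hits "
      f"({int(hits['is_contaminant'].sum())} contaminants), "
      f"{len(surveys)} survey rows -> {OUT}")
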