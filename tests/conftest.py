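import numpy as np
import pandas as pd
import pytest

from trophimix import synthetic


@pytest.fixture
def scenario():
    return synthetic.default_scenario(seed=42)


@pytest.fixture
def two_group_scenario():
    """Minimal 3-category scenario with simple round numbers."""
    cats = ["Caesionidae", "Pomacentridae", "Labridae"]
    return synthetic.TruthScenario(
        prey_categories=cats,
        true_diet={"pred": np.array([0.5, 0.3, 0.2])},
        empty_stomach_prob=0.0,
        source_means=np.array([[-18.0, 8.0], [-12.0, 10.0], [-15.0, 15.0]]),
        source_sds=np.full((3, 2), 0.5),
        tdf_means={"muscle": np.array([1.0, 2.0])},
        tdf_sds={"muscle": np.array([0.2, 0.2])},
        residual_sd=np.array([0.3, 0.3]),
        env_proportions={
            "r1": np.array([0.2, 0.5, 0.3]),
            "r2": np.array([0.25, 0.45, 0.3]),
        },
        contamination_rate=0.2,
        seed=7,
    )


@pytest.fixture
def table2_records():
    """Prey records reconstructed from the published visual-contents table.

    Item counts per family (38 items) and stomach occurrences per family
    (31 stomachs with identifiable prey) are the integer bases of the
    printed %N and %O rows; records are laid out so both marginals hold.
    """
    families = [
        "Caesionidae", "Labridae", "Pomacentridae", "Labridae (Scarinae)",
        "Acanthuridae", "Serranidae", "Siganidae", "Crustacea",
        "Gobiidae", "Apogonidae",
    ]
    items = [10, 9, 9, 2, 1, 2, 1, 2, 1, 1]          # sums to 38
    occurrences = [10, 8, 6, 2, 1, 2, 1, 2, 1, 1]    # over 31 stomachs
    rows = []
    sid = 0
    stomach_of_family = {}
    for fam, n_items, n_st in zip(families, items, occurrences):
        ids = []
        for _ in range(n_st):
            ids.append(f"st{sid:03d}")
            sid += 1
        stomach_of_family[fam] = ids
        # place one item per occupied stomach, extras in the first stomach
        for j in range(n_items):
            stomach = ids[j] if j < n_st else ids[0]
            rows.append(
                {
                    "stomach_id": stomach,
                    "predator_group": "Plectropomus",
                    "prey_taxon": fam,
                    "prey_category": fam,
                    "digestion_level": 3,
                    "weight": np.nan,
                    "method": "visual",
                }
            )
    df = pd.DataFrame(rows)
    # reuse stomachs across families so the total distinct count is 31:
    # remap surplus stomach ids onto the first 31
    uniq = df["stomach_id"].unique()
    if len(uniq) > 31:
        base = list(uniq[:31])
        mapping = {u: base[i % 31] for i, u in enumerate(uniq)}
        # remapping must not merge two stomachs of the same family (would
        # change occurrence counts); verify and fall back to identity
        trial = df.assign(stomach_id=df["stomach_id"].map(mapping))
        occ = trial.groupby("prey_category")["stomach_id"].nunique()
        want = dict(zip(families, occurrences))
        if all(occ[f] == want[f] for f in families):
            df = trial
    return df
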