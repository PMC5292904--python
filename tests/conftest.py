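import numpy as np
import pandas as pd
import pytest

from fmstab import CommunityTable, validate_metadata
from fmstab.trees import read_tree_string

FIXTURE_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def four_tip_tree():
    return read_tree_string(FIXTURE_NEWICK)


@pytest.fixture
def tiny_counts():
    frame = pd.DataFrame(
        [[5, 10], [3, 0], [2, 0]],
        index=["otu_a", "otu_b", "otu_c"],
        columns=["s1", "s2"],
        dtype=float,
    )
    return CommunityTable(frame, mode="counts")


def make_table(values, otu_ids=None, sample_ids=None, mode="counts"):
    values = np.asarray(values, dtype=float)
    otu_ids = otu_ids or [f"otu_{k + 1}" for k in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(values.shape[1])]
    return CommunityTable(
        pd.DataFrame(values, index=otu_ids, columns=sample_ids), mode=mode
    )


def make_metadata(rows):
    """Build a typed metadata frame from a list of dicts (sample_id key)."""
    frame = pd.DataFrame(rows)
    return validate_metadata(frame)


@pytest.fixture
def adult_metadata():
    """Six adults, two colonies, two years, two samples per adult per year."""
    rows = []
    s = 0
    for a in range(6):
        colony = "C1" if a < 3 else "C2"
        for year in (2013, 2014):
            for _ in range(2):
                s += 1
                rows.append({
                    "sample_id": f"s{s}", "individual_id": f"A{a + 1}",
                    "cohort": "adult", "colony_id": colony, "year": year,
                    "sex": "F" if a % 2 == 0 else "M",
                })
    return make_metadata(rows)


@pytest.fixture
def family_metadata():
    """Two colonies x two nests x two juveniles (3 age-classes) plus parents."""
    rows = []
    s = 0
    for c in range(2):
        colony = f"C{c + 1}"
        females = [f"F{c}{t}" for t in range(2)]
        males = [f"M{c}{t}" for t in range(2)]
        for ind in females + males:
            for _ in range(2):
                s += 1
                rows.append({
                    "sample_id": f"s{s}", "individual_id": ind,
                    "cohort": "adult", "colony_id": colony, "year": 2014,
                    "sex": "F" if ind.startswith("F") else "M",
                })
        for t in range(2):
            nest = f"{colony}_N{t + 1}"
            for u in range(2):
                juv = f"J{c}{t}{u}"
                for age in (6, 9, 12):
                    s += 1
                    rows.append({
                        "sample_id": f"s{s}", "individual_id": juv,
                        "cohort": "juvenile", "age_class": age,
                        "nest_id": nest, "colony_id": colony, "year": 2014,
                        "social_mother_id": females[t],
                        "social_father_id": males[t],
                        "is_extra_pair": u == 1 and t == 0 and c == 0,
                        "is_parasitic": u == 1 and t == 1 and c == 1,
                    })
    return make_metadata(rows)
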