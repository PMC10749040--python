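import numpy as np
import pandas as pd
import pytest

from racemix import names, synth


@pytest.fixture(scope="session")
def name_table():
    return synth.generate_name_table(40, (1950, 2005), seed=11)


@pytest.fixture(scope="session")
def small_truth():
    return synth.SyntheticTruth(
        n_athletes=500,
        frac_nonbinary=0.08,
        seed=7,
        event_log_means=synth.default_event_log_means(5),
    )


@pytest.fixture(scope="session")
def athletes(small_truth, name_table):
    return synth.generate_athletes(small_truth, name_table, seed=13)


@pytest.fixture(scope="session")
def results(small_truth, athletes):
    return synth.generate_race_results(
        athletes, small_truth, races_per_athlete=2, seed=17, marathon_frac=0.5
    )


@pytest.fixture(scope="session")
def assigned(results, athletes, name_table):
    """One-race-per-athlete table with prob_male assigned from all sources."""
    lookup = synth.generate_lookup(athletes, coverage=0.6, seed=19)
    out, _ = names.assign_probabilities(results, lookup, name_table)
    out = out[out["prob_source"] != "none"]
    # keep one record per athlete (fastest) so models see independent rows
    out = out.loc[out.groupby("name")["time_seconds"].idxmin()]
    return out.reset_index(drop=True)


def make_degenerate(df: pd.DataFrame) -> pd.DataFrame:
    """Force every prob_male to 0/1 (declared-only view of a dataset)."""
    out = df.copy()
    out["prob_male"] = np.where(out["prob_male"] >= 0.5, 1.0, 0.0)
    return out
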