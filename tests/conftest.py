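import pandas as pd
import pytest

from weightregain.study_corpus import CSV_COLUMNS, DifferenceSeries, corpus_from_frame
from weightregain.synthetic_data import CorpusParams, generate_corpus, generate_epi


def make_rows(*rows):
    """Schema-conformant frame from (study, arm, role, pe, t, mean, sd, n) tuples."""
    recs = []
    for study, arm, role, pe, t, mean, sd, n in rows:
        recs.append(
            {
                "study_id": study,
                "arm_id": arm,
                "arm_role": role,
                "rob_overall": "low",
                "programme_end_month": pe,
                "t_months": t,
                "mean_change_kg": mean,
                "sd_kg": sd,
                "n_analyzed": n,
                "qol_scale": None,
                "qol_direction": None,
                "qol_mean_change": None,
                "qol_sd": None,
            }
        )
    return pd.DataFrame(recs, columns=CSV_COLUMNS)


def linear_series(study_id, a, slope, ts, var=0.04, n=100, max_fu=None):
    """Exact linear difference series D(t) = a + slope*t."""
    pts = tuple((float(t), float(a + slope * t), var, n) for t in ts)
    fu = max_fu if max_fu is not None else 6.0 + max(ts)
    return DifferenceSeries(study_id, "weight_kg", pts, max_followup_months=fu)


@pytest.fixture(scope="session")
def corpus_seed7():
    """50 synthetic studies, true slope 0.027 kg/month (session-cached)."""
    df = generate_corpus(CorpusParams(n_studies=50, seed=7))
    return corpus_from_frame(df)


@pytest.fixture(scope="session")
def toy_epi():
    return generate_epi(3)
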