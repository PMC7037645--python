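import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "kidfit",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("kidfit")

from kidfit import CohortConfig, ConfusionTable, generate_cohort  # noqa: E402

#: Published 2x2 cell counts of the screening-validation table, by state.
PRINTED_COUNTS = {
    "overweight_obese": (6, 0, 4, 15),
    "lowest_motor_quartile": (9, 1, 12, 35),
    "reduced_crf": (7, 0, 3, 14),
}


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def lms_table(tmp_path_factory):
    """Small synthetic LMS reference table (BMI-for-age-like shape)."""
    path = tmp_path_factory.mktemp("lms") / "lms_synthetic.csv"
    rows = []
    for sex in ("female", "male"):
        for agemos in (120, 132, 144, 156, 168):
            rows.append(
                {
                    "sex": sex,
                    "agemos": agemos,
                    "L": -1.5 + 0.002 * (agemos - 120),
                    "M": 17.0 + 0.02 * (agemos - 120) + (0.3 if sex == "male" else 0.0),
                    "S": 0.12 + 0.0001 * (agemos - 120),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def brute_force_fisher(tp: int, fn: int, fp: int, tn: int) -> float:
    """Independent enumeration oracle for the two-sided exact test.

    Enumerates every 2x2 table with the observed margins using binomial
    coefficients only, and sums point probabilities <= the observed one.
    """
    from math import comb

    n = tp + fn + fp + tn
    k = tp + fn          # diseased margin
    m = tp + fp          # screen-positive margin
    denom = comb(n, m)
    probs = []
    for x in range(max(0, m - (n - k)), min(k, m) + 1):
        probs.append(comb(k, x) * comb(n - k, m - x) / denom)
    p_obs = comb(k, tp) * comb(n - k, m - tp) / denom
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))


def all_pairs_auc(scores, diseased) -> float:
    """Exhaustive Mann-Whitney AUC oracle: ties count one half."""
    scores = np.asarray(scores, float)
    diseased = np.asarray(diseased, bool)
    pos = scores[diseased]
    neg = scores[~diseased]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
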