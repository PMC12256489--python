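import numpy as np
import pytest

from pertdm import ModelConfig, OutcomeTable, ParameterTable


@pytest.fixture(scope="session")
def table() -> ParameterTable:
    return ParameterTable.from_csv()


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def study_outcomes() -> OutcomeTable:
    """The published 12-month completer counts (uncontrolled, response, seizure-free),
    with the non-TDM uncontrolled count reconciled against the published n and rates."""
    from pertdm.clinical import STUDY_OUTCOME_COUNTS_12M
    return OutcomeTable.from_counts(tdm=STUDY_OUTCOME_COUNTS_12M["tdm"],
                                    nontdm=STUDY_OUTCOME_COUNTS_12M["nontdm"])


def po_loglik(counts_tdm, counts_nontdm, beta, c1, c2) -> float:
    """Independent cumulative-logit log-likelihood for a 2x3 table.

    P(y <= j | x) = logistic(c_j - beta * x), x = 1 for the non-TDM arm.
    Written without statsmodels so it can serve as an oracle for the MLE.
    """
    def probs(x):
        q1 = 1.0 / (1.0 + np.exp(-(c1 - beta * x)))
        q2 = 1.0 / (1.0 + np.exp(-(c2 - beta * x)))
        return np.array([q1, q2 - q1, 1.0 - q2])

    ll = 0.0
    for x, counts in ((0.0, counts_tdm), (1.0, counts_nontdm)):
        p = probs(x)
        if np.any(p <= 0):
            return -np.inf
        ll += float(np.dot(counts, np.log(p)))
    return ll


def po_grid_search(counts_tdm, counts_nontdm, rounds: int = 5, width: int = 13):
    """Nested grid search maximizing the cumulative-logit likelihood.

    Refines a (beta, c1, dc) grid around the running optimum; resolves the
    log-likelihood to well below 1e-6 after five shrinking rounds.
    """
    t = np.asarray(counts_tdm, float)
    n = np.asarray(counts_nontdm, float)
    center = np.array([0.0, 0.0, 1.0])   # beta, c1, log-ish gap via dc > 0
    span = np.array([4.0, 4.0, 4.0])
    best = (-np.inf, center)
    for _ in range(rounds):
        grids = [np.linspace(c - s, c + s, width) for c, s in zip(center, span)]
        for b in grids[0]:
            for c1 in grids[1]:
                for dc in grids[2]:
                    if dc <= 0:
                        continue
                    ll = po_loglik(t, n, b, c1, c1 + dc)
                    if ll > best[0]:
                        best = (ll, np.array([b, c1, dc]))
        center = best[1]
        span = span * (2.2 / (width - 1))
    ll, (b, c1, dc) = best
    return {"loglik": ll, "beta": b, "cutpoints": (c1, c1 + dc)}
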