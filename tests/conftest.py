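import pytest

from exposim.engine import SessionConfig
from exposim.hierarchy import load_hierarchy


@pytest.fixture(scope="session")
def default_hierarchy():
    return load_hierarchy()


@pytest.fixture(scope="session")
def default_config():
    return SessionConfig()


def tick_oracle(initial_position, decisions, cfg=SessionConfig(), elicitation=None):
    """Independent hand-stepped simulator used as the oracle for SUDS traces.

    A plain second-by-second loop over the tick grid, written without any
    engine code: ``decisions`` are the positions chosen at decision points
    2..n (the initial selection is decision 1).  Returns the (t, suds) pairs
    at habituation drops plus the final (t, suds).
    """
    if elicitation is None:
        elicitation = lambda p: max(cfg.suds_min, min(cfg.suds_max, p))
    position = initial_position
    suds = elicitation(position)
    time_on_task = 0
    trace = [(0, suds)]
    t = 0
    decision_iter = iter(decisions)
    next_decision_t = cfg.decision_interval_seconds
    n_left = cfg.n_decision_points - 1
    end_t = cfg.n_decision_points * cfg.decision_interval_seconds
    while t < end_t:
        t += cfg.tick_seconds
        time_on_task += cfg.tick_seconds
        if time_on_task % cfg.habituation_interval_seconds == 0 and suds > cfg.suds_min:
            suds -= 1
            trace.append((t, suds))
        if t == next_decision_t and n_left > 0:
            choice = next(decision_iter)
            if choice > position:
                suds = elicitation(choice)
            elif choice < position:
                suds = min(suds, elicitation(choice))
            if choice != position:
                position = choice
                time_on_task = 0
            next_decision_t += cfg.decision_interval_seconds
            n_left -= 1
    return trace, (t, suds)
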