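import numpy as np
import pandas as pd
import pytest

import pignet as pn
from pignet.pipeline import analyse_networks, assemble_analysis_table


@pytest.fixture(scope="session")
def eth():
    return pn.default_ethogram()


@pytest.fixture()
def toy_roster():
    """One pen of six pigs; A and B are littermates, the rest singletons."""
    rows = []
    for pig, litter in [
        ("A", "L1"),
        ("B", "L1"),
        ("C", "L2"),
        ("D", "L3"),
        ("E", "L4"),
        ("F", "L5"),
    ]:
        rows.append(
            {
                "pig_id": pig,
                "pen_id": "pen1",
                "litter_id": litter,
                "sex": "F",
                "weight_kg": 60.0,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_study():
    """A 4-pen synthetic study shared by invariant-style tests."""
    return pn.generate_study(n_pens=4, seed=7)


@pytest.fixture(scope="session")
def small_study_events(small_study):
    from pignet.synthetic import _frame_to_event_list

    return _frame_to_event_list(small_study.events)


@pytest.fixture(scope="session")
def analysis_table(small_study):
    cent = analyse_networks(small_study.roster, small_study.events)
    return assemble_analysis_table(
        small_study.roster, cent, small_study.trials, small_study.lesions
    )


def make_net(graph, net_type="ALL", n_nonlittermates=None):
    """Wrap a bare networkx graph as an AgonisticNetwork for centrality
    tests, filling in the node attributes centrality needs."""
    from pignet.networks import AgonisticNetwork

    for node in graph.nodes:
        nn = (
            n_nonlittermates
            if n_nonlittermates is not None
            else graph.number_of_nodes() - 1
        )
        graph.nodes[node]["n_nonlittermates"] = nn
    return AgonisticNetwork(net_type, graph)
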