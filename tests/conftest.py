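from datetime import datetime

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from carenet.records import CareActivityRecord, RecordSet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def sample_records() -> RecordSet:
    """The four-row example record set used throughout the docs."""
    rows = [
        ("P_00001", "Conduct an admission discussion", "2019-03-22 08:00:00", 1, 15.0),
        ("P_00001", "Supporting breastfeeding", "2019-04-22 08:00:00", 1, 9.0),
        ("P_00002", "Conduct an admission discussion", "2019-05-14 08:00:00", 1, 5.0),
        ("P_00002", "Monitoring the state of the uterus", "2019-05-14 20:15:00", 1, 2.0),
    ]
    records = tuple(
        CareActivityRecord(
            case_id=cid,
            activity=act,
            timestamp=datetime.strptime(ts, "%Y-%m-%d %H:%M:%S"),
            n_providers=n,
            care_time=ct,
        )
        for cid, act, ts, n, ct in rows
    )
    return RecordSet(records, source="sample")


@pytest.fixture
def sample_csv(tmp_path, sample_records):
    from carenet.records import write_records

    path = tmp_path / "records.csv"
    write_records(sample_records, path)
    return path


@pytest.fixture
def star_graph() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(("hub", f"leaf{i}") for i in range(5))
    return g


@pytest.fixture
def two_cliques() -> nx.Graph:
    """Two disjoint 4-cliques."""
    g = nx.Graph()
    for offset in ("a", "b"):
        nodes = [f"{offset}{i}" for i in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(nodes[i], nodes[j])
    return g
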