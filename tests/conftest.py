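import pytest
from hypothesis import HealthCheck, settings

from hetesim import Fixture, figure1_graph, make_random_hin

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fig1() -> Fixture:
    return figure1_graph()


def _layer_spec(n_layers: int, size: int) -> list[tuple[str, int]]:
    return [(f"L{i + 1}", size) for i in range(n_layers)]


@pytest.fixture(scope="session")
def random_fixtures() -> list[Fixture]:
    """Assorted random layered graphs: metapath lengths 2-5, with and
    without seeded dead ends."""
    cases = [
        (3, 3, 0.7, 0.0, 11),
        (3, 4, 0.5, 0.3, 12),
        (4, 3, 0.6, 0.0, 13),
        (4, 4, 0.5, 0.25, 14),
        (5, 3, 0.6, 0.2, 15),
        (5, 4, 0.4, 0.3, 16),
        (6, 3, 0.6, 0.2, 17),
    ]
    return [
        make_random_hin(_layer_spec(n_layers, size), edge_prob=p,
                        dead_end_bias=bias, seed=seed)
        for n_layers, size, p, bias, seed in cases
    ]


@pytest.fixture(scope="session")
def short_random_fixtures(random_fixtures) -> list[Fixture]:
    """The random fixtures whose metapath length is at most 4."""
    return [f for f in random_fixtures if f.metapath.length <= 4]
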