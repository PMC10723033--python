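import numpy as np
import pytest

from spotglass.core import AnnotationColumn, PointTable


def make_table(n=3, coord_mode="cartesian", **columns):
    """Tiny table builder: columns given as name=(kind, values)."""
    ids = [f"p{i}" for i in range(n)]
    rng = np.random.default_rng(0)
    table = PointTable(
        point_ids=ids,
        x=np.arange(n, dtype=float),
        y=rng.uniform(0, 1, size=n),
        coord_mode=coord_mode,
    )
    for name, (kind, values) in columns.items():
        table = table.with_annotation(
            AnnotationColumn.from_raw(name, values, kind=kind)
        )
    return table


@pytest.fixture
def three_point_table():
    return make_table(
        3,
        domain=("categorical", ["L1", "L2", "L1"]),
        expr=("continuous", [0.5, 1.5, 2.5]),
    )
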