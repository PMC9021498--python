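"""Built-in example datasets and fixture generation.

``trust_survey_example`` is the published illustrative portion of an
interpersonal trust survey: 4 group members, two trust dimensions
(affect-based, items 1-3; cognition-based, items 4-6), every ordered pair
rated on a 1-7 scale.  The other fixtures are synthetic: a 3-member toy
(one item per dimension) and a 15-member, 6-item set with the shape of
the full empirical design.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .data import DyadicResponseTable
from .simulate import SimConfig, draw_parameters, generate_dataset

__all__ = ["trust_survey_example", "make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("table1", "tiny", "empirical-shaped")

# (sender, receiver) -> responses to items 1..6
_TRUST_ROWS = {
    (1, 2): (3, 4, 2, 4, 2, 4),
    (2, 1): (5, 3, 4, 3, 3, 5),
    (1, 3): (3, 3, 4, 4, 3, 3),
    (3, 1): (5, 4, 3, 1, 2, 2),
    (1, 4): (3, 4, 3, 2, 3, 4),
    (4, 1): (2, 3, 2, 3, 5, 1),
    (2, 3): (3, 4, 2, 4, 3, 3),
    (3, 2): (3, 5, 4, 4, 5, 4),
    (2, 4): (6, 3, 4, 1, 3, 3),
    (4, 2): (3, 4, 3, 3, 4, 3),
    (3, 4): (4, 4, 6, 3, 4, 5),
    (4, 3): (3, 4, 3, 3, 4, 4),
}


def trust_survey_example() -> DyadicResponseTable:
    """The 4-member interpersonal-trust example as a validated table
    (72 directed responses; L=2 subscales of I=3 items)."""
    rows = []
    for (s, r), resp in _TRUST_ROWS.items():
        for item, y in enumerate(resp, start=1):
            rows.append({"sender": s, "receiver": r,
                         "subscale": 1 if item <= 3 else 2,
                         "item": item, "response": float(y)})
    return DyadicResponseTable(pd.DataFrame(rows))


def make_fixture(kind: str, seed: int, out_dir: str | Path) -> Path:
    """Write a fixture dataset as a long-format CSV; returns the path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "table1":
        table = trust_survey_example()
    elif kind == "tiny":
        cfg = SimConfig(n_members=3, n_subscales=2, items_per_subscale=1)
        table = generate_dataset(draw_parameters(cfg, seed), cfg, seed + 1)
    elif kind == "empirical-shaped":
        cfg = SimConfig(n_members=15, n_subscales=2, items_per_subscale=3)
        table = generate_dataset(draw_parameters(cfg, seed), cfg, seed + 1)
    else:
        raise ValueError(f"unknown fixture kind: {kind!r} "
                         f"(choose from {FIXTURE_KINDS})")
    path = out_dir / f"{kind.replace('-', '_')}.csv"
    table.write_csv(path)
    return path
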