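"""Round-robin dyadic response data: containers, validation, conversions.

The observed data for a latent interdependence analysis are directed item
responses: every member of an ``n``-person network rates every other member
on ``T = I * L`` items, where the ``T`` items partition into ``L`` subscales
(one per latent trait dimension) of ``I`` items each.  A complete design
therefore holds ``n * (n - 1) * T`` responses.

Three views of the same data are supported:

* a long-format table (one row per directed response), the on-disk format;
* a per-dyad ``T x 2`` matrix (column 1 = the lexicographically smaller
  member acting as rating sender, column 2 = the other member as sender);
* an ``n x n`` sociomatrix of per-subscale summed scores (zero diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NetworkSpec",
    "DyadicResponseTable",
    "DyadMatrixPair",
    "enumerate_dyads",
    "read_long_table",
    "reverse_score",
    "sociomatrix_to_frame",
    "InvalidNetworkError",
    "DuplicateRecordError",
    "SelfRatingError",
    "MissingDataError",
]

LONG_COLUMNS = ["sender", "receiver", "subscale", "item", "response"]


class InvalidNetworkError(ValueError):
    """Network too small or structurally invalid."""


class DuplicateRecordError(ValueError):
    """The same (sender, receiver, item) triple appears more than once."""


class SelfRatingError(ValueError):
    """A member rated themselves; self-ratings are undefined by convention."""


class MissingDataError(ValueError):
    """The design is not a complete round robin (missing-data handling is
    out of scope; incomplete designs are rejected, not imputed)."""


def enumerate_dyads(n: int) -> list[tuple[int, int]]:
    """All unordered member pairs of an ``n``-member network.

    Pairs are 1-based ``(A, B)`` with ``A < B``, in row-major order of the
    upper triangle, so dyad ``d`` (0-based position in the returned list)
    is a reproducible index shared with the sociomatrix convention.

    >>> enumerate_dyads(2)
    [(1, 2)]
    """
    if n < 2:
        raise InvalidNetworkError(f"a network needs at least 2 members, got n={n}")
    return [(a, b) for a in range(1, n + 1) for b in range(a + 1, n + 1)]


def reverse_score(y: float, scale_min: float, scale_max: float) -> float:
    """Reverse-score a response on a bounded rating scale.

    Needed when an instrument mixes positively and negatively keyed items:
    the receiver-effect sign constraint assumes a higher response implies a
    higher receiver trait, so negatively keyed items must be flipped first.
    """
    if not (scale_min <= y <= scale_max):
        raise ValueError(
            f"response {y} outside scale [{scale_min}, {scale_max}]"
        )
    return scale_min + scale_max - y


@dataclass(frozen=True)
class NetworkSpec:
    """Structural description of a round-robin measurement design.

    Parameters
    ----------
    member_ids : ordered unique member labels (n >= 2).
    item_to_subscale : for each of the T items (in item order), the 1-based
        index of the subscale / latent dimension it measures.  Each item
        measures exactly one trait.
    """

    member_ids: tuple
    item_to_subscale: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.member_ids)) != len(self.member_ids):
            raise InvalidNetworkError("member ids must be unique")
        if len(self.member_ids) < 2:
            raise InvalidNetworkError("need at least 2 members")
        subs = sorted(set(self.item_to_subscale))
        if subs != list(range(1, len(subs) + 1)):
            raise InvalidNetworkError(
                f"subscale indices must be 1..L without gaps, got {subs}"
            )

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_subscales(self) -> int:
        return max(self.item_to_subscale)

    @property
    def n_items(self) -> int:
        """Total item count T."""
        return len(self.item_to_subscale)

    @property
    def items_per_subscale(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.item_to_subscale:
            out[s] = out.get(s, 0) + 1
        return out

    @property
    def n_dyads(self) -> int:
        return self.n_members * (self.n_members - 1) // 2

    def dyads(self) -> list[tuple]:
        """Unordered member-id pairs, in the canonical dyad order."""
        ids = list(self.member_ids)
        return [(ids[a - 1], ids[b - 1]) for a, b in enumerate_dyads(self.n_members)]

    @classmethod
    def balanced(cls, n_members: int, n_subscales: int, items_per_subscale: int,
                 member_ids: Sequence | None = None) -> "NetworkSpec":
        """Spec for the common balanced design: L subscales of I items each."""
        if member_ids is None:
            member_ids = tuple(range(1, n_members + 1))
        sub = tuple(
            s for s in range(1, n_subscales + 1) for _ in range(items_per_subscale)
        )
        return cls(tuple(member_ids), sub)

    def expected_rows(self) -> int:
        return self.n_members * (self.n_members - 1) * self.n_items


@dataclass(frozen=True)
class DyadMatrixPair:
    """Both members' responses for one dyad, stacked item-wise.

    ``V`` is ``T x 2``: column 0 holds member A's ratings of B (A the
    lexicographically smaller member, acting as sender), column 1 holds B's
    ratings of A.  Rows follow item order, i.e. the L subscale blocks ``U``
    (each ``I x 2``) in subscale order.
    """

    members: tuple
    V: np.ndarray
    item_to_subscale: tuple[int, ...]

    def U(self, subscale: int) -> np.ndarray:
        """The ``I x 2`` block of one subscale."""
        mask = np.asarray(self.item_to_subscale) == subscale
        if not mask.any():
            raise KeyError(f"no such subscale: {subscale}")
        return self.V[mask]


class DyadicResponseTable:
    """Validated long-format table of directed item responses.

    One row per (sender, receiver, item) with the continuous response in
    the instrument's scale units.  Construction enforces the complete
    round-robin contract: no self-ratings, no duplicated directed cells,
    and (by default) every ordered pair x item cell present.
    """

    def __init__(self, frame: pd.DataFrame, spec: NetworkSpec | None = None,
                 require_complete: bool = True):
        frame = frame.copy()
        missing_cols = [c for c in LONG_COLUMNS if c not in frame.columns]
        if missing_cols:
            raise ValueError(f"long table missing columns {missing_cols}")
        frame = frame[LONG_COLUMNS]
        frame["response"] = frame["response"].astype(float)

        if (frame["sender"] == frame["receiver"]).any():
            bad = frame.loc[frame["sender"] == frame["receiver"]].iloc[0]
            raise SelfRatingError(
                f"self-rating rows are invalid (member {bad['sender']})"
            )
        dup = frame.duplicated(subset=["sender", "receiver", "item"])
        if dup.any():
            bad = frame.loc[dup].iloc[0]
            raise DuplicateRecordError(
                "duplicated (sender, receiver, item) triple: "
                f"({bad['sender']}, {bad['receiver']}, {bad['item']})"
            )

        if spec is None:
            spec = self._infer_spec(frame)
        self.spec = spec
        id_pos = {m: k for k, m in enumerate(spec.member_ids)}
        unknown = set(frame["sender"]) | set(frame["receiver"])
        unknown -= set(spec.member_ids)
        if unknown:
            raise InvalidNetworkError(f"members not in spec: {sorted(unknown)}")

        # canonical ordering: sender, receiver, item (positions in spec)
        frame["_s"] = frame["sender"].map(id_pos)
        frame["_r"] = frame["receiver"].map(id_pos)
        frame = frame.sort_values(["_s", "_r", "item"], kind="mergesort")
        self._frame = frame.drop(columns=["_s", "_r"]).reset_index(drop=True)

        self.completeness = len(frame) / spec.expected_rows()
        if require_complete and len(frame) != spec.expected_rows():
            raise MissingDataError(
                f"incomplete round robin: {len(frame)} of "
                f"{spec.expected_rows()} directed response cells present "
                f"(completeness {self.completeness:.3f}); missing data are "
                "not supported"
            )

    @staticmethod
    def _infer_spec(frame: pd.DataFrame) -> NetworkSpec:
        members = tuple(sorted(set(frame["sender"]) | set(frame["receiver"])))
        item_sub = (
            frame[["item", "subscale"]].drop_duplicates().sort_values("item")
        )
        if item_sub["item"].duplicated().any():
            raise InvalidNetworkError("an item maps to more than one subscale")
        return NetworkSpec(members, tuple(int(s) for s in item_sub["subscale"]))

    # ------------------------------------------------------------------ views
    def to_dataframe(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def items(self) -> list:
        return sorted(self._frame["item"].unique())

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(sender_idx, receiver_idx, item_idx, response) as 0-based arrays,
        the flat representation consumed by the likelihood and the sampler."""
        f = self._frame
        id_pos = {m: k for k, m in enumerate(self.spec.member_ids)}
        item_pos = {it: k for k, it in enumerate(self.items)}
        s = f["sender"].map(id_pos).to_numpy(dtype=np.int64)
        r = f["receiver"].map(id_pos).to_numpy(dtype=np.int64)
        i = f["item"].map(item_pos).to_numpy(dtype=np.int64)
        y = f["response"].to_numpy(dtype=np.float64)
        return s, r, i, y

    def dyad_matrix(self, dyad: int | tuple) -> DyadMatrixPair:
        """The ``T x 2`` response matrix of one dyad.

        ``dyad`` is either a 0-based dyad index (canonical upper-triangle
        order) or a member-id pair.
        """
        if isinstance(dyad, (int, np.integer)):
            pairs = self.spec.dyads()
            if not 0 <= dyad < len(pairs):
                raise IndexError(f"dyad index {dyad} out of range")
            a_id, b_id = pairs[dyad]
        else:
            a_id, b_id = sorted(dyad, key=list(self.spec.member_ids).index)
        f = self._frame
        T = self.spec.n_items
        items = self.items
        V = np.full((T, 2), np.nan)
        for col, (snd, rcv) in enumerate([(a_id, b_id), (b_id, a_id)]):
            rows = f[(f["sender"] == snd) & (f["receiver"] == rcv)]
            got = rows.set_index("item")["response"]
            for t, it in enumerate(items):
                if it in got.index:
                    V[t, col] = got.loc[it]
        if np.isnan(V).any():
            raise MissingDataError(f"dyad ({a_id}, {b_id}) has missing responses")
        return DyadMatrixPair((a_id, b_id), V, self.spec.item_to_subscale)

    def sociomatrix(self, subscale: int | None = None) -> np.ndarray:
        """Directed summed-score network: entry (S, R) is the sum of S's
        responses about R over the items of ``subscale`` (all items when
        None).  Diagonal fixed at 0 by convention."""
        s, r, i, y = self.arrays()
        if subscale is not None:
            sub = np.asarray(self.spec.item_to_subscale)[i]
            keep = sub == subscale
            if not keep.any():
                raise KeyError(f"no such subscale: {subscale}")
            s, r, y = s[keep], r[keep], y[keep]
        n = self.spec.n_members
        Y = np.zeros((n, n))
        np.add.at(Y, (s, r), y)
        return Y

    # ------------------------------------------------------------------- io
    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        self._frame.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_arrays(cls, spec: NetworkSpec, s: np.ndarray, r: np.ndarray,
                    i: np.ndarray, y: np.ndarray) -> "DyadicResponseTable":
        """Inverse of :meth:`arrays` (0-based index arrays back to a table)."""
        ids = pd.Series(list(spec.member_ids))
        subs = np.asarray(spec.item_to_subscale)
        frame = pd.DataFrame({
            "sender": ids.iloc[np.asarray(s)].to_numpy(),
            "receiver": ids.iloc[np.asarray(r)].to_numpy(),
            "subscale": subs[np.asarray(i)],
            "item": np.asarray(i) + 1,
            "response": np.asarray(y, dtype=float),
        })
        return cls(frame, spec=spec)


def read_long_table(path: str | Path, sep: str | None = None,
                    require_complete: bool = True) -> DyadicResponseTable:
    """Read a delimited long-format response file (CSV/TSV autodetected).

    Expects header columns sender, receiver, subscale, item, response; an
    optional dyad column is ignored and recomputed from the canonical
    upper-triangle ordering.
    """
    frame = pd.read_csv(path, sep=sep, engine="python")
    frame.columns = [c.strip().lower() for c in frame.columns]
    frame = frame.drop(columns=[c for c in ("dyad",) if c in frame.columns])
    return DyadicResponseTable(frame, require_complete=require_complete)


def sociomatrix_to_frame(Y: np.ndarray, member_ids: Sequence) -> pd.DataFrame:
    """Dense sociomatrix as a labelled DataFrame (member ids as header
    row/column), the CSV export layout."""
    return pd.DataFrame(Y, index=list(member_ids), columns=list(member_ids))
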