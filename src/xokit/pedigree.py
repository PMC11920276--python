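"""Pedigree container shared by the simulator and the quantitative-genetics code.

Individuals are integer ids >= 1; unknown parents are coded 0.  Rows are
kept in a topological order (parents before offspring), which is validated
on construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class Pedigree:
    COLUMNS = ("id", "sire", "dam", "sex")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        df = df.reset_index(drop=True)
        ids = df["id"].to_numpy(dtype=np.int64)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in pedigree")
        seen: set[int] = set()
        for i, s, d in zip(ids, df["sire"].to_numpy(np.int64), df["dam"].to_numpy(np.int64)):
            for parent in (s, d):
                if parent != 0 and parent not in seen:
                    if parent == i:
                        raise ValueError(f"individual {i} is its own parent")
                    raise ValueError(
                        f"pedigree not topologically ordered (or cyclic): parent {parent} "
                        f"of {i} not listed earlier"
                    )
            seen.add(int(i))
        self.df = df
        self.ids = ids
        self.sire = df["sire"].to_numpy(np.int64)
        self.dam = df["dam"].to_numpy(np.int64)
        self.sex = df["sex"].to_numpy(object)
        self._row = {int(i): r for r, i in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def row_of(self, ind: int) -> int:
        return self._row[int(ind)]

    def is_founder(self, ind: int) -> bool:
        r = self.row_of(ind)
        return self.sire[r] == 0 and self.dam[r] == 0

    def parents(self, ind: int) -> tuple[int, int]:
        r = self.row_of(ind)
        return int(self.sire[r]), int(self.dam[r])

    def sex_of(self, ind: int) -> str:
        return str(self.sex[self.row_of(ind)])

    def offspring_of(self, ind: int) -> list[int]:
        mask = (self.sire == ind) | (self.dam == ind)
        return [int(i) for i in self.ids[mask]]

    def founders(self) -> np.ndarray:
        return self.ids[(self.sire == 0) & (self.dam == 0)]

    def non_founders(self) -> np.ndarray:
        return self.ids[(self.sire != 0) | (self.dam != 0)]

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients by the recursive tabular method (dense)."""
        n = len(self)
        A = np.zeros((n, n))
        srow = np.array([self._row.get(int(s), -1) for s in self.sire])
        drow = np.array([self._row.get(int(d), -1) for d in self.dam])
        for i in range(n):
            s, d = srow[i], drow[i]
            A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
            for j in range(i):
                a = 0.0
                if s >= 0:
                    a += 0.5 * A[j, s]
                if d >= 0:
                    a += 0.5 * A[j, d]
                A[i, j] = A[j, i] = a
        return np.diag(A) - 1.0
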