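"""Species-pair divergence times (Myr since the most recent common ancestor).

Pairwise rates are normalised by T, the time back to the MRCA of the two
species, not by the total branch-path length 2T.  Dates come either from a
published table (TSV: species_a, species_b, T_myr) or from a dated tree.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ParameterError, SpeciesLookupError


class DivergenceTable:
    """Symmetric lookup of Myr-since-MRCA for species pairs."""

    def __init__(self, times: dict[tuple[str, str], float]):
        self._times: dict[frozenset, float] = {}
        for (a, b), t in times.items():
            if t <= 0:
                raise ParameterError(f"divergence time for ({a},{b}) must be > 0")
            self._times[frozenset((a, b))] = float(t)

    def time(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in self._times:
            raise SpeciesLookupError(f"no divergence time for pair ({a}, {b})")
        return self._times[key]

    def pairs(self) -> list[tuple[str, str]]:
        return [tuple(sorted(k)) for k in self._times]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species_a": a, "species_b": b, "T_myr": self.time(a, b)}
            for a, b in sorted(self.pairs())
        ]
        return pd.DataFrame(rows, columns=["species_a", "species_b", "T_myr"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DivergenceTable":
        frame = pd.read_csv(path, sep="\t")
        required = {"species_a", "species_b", "T_myr"}
        if not required <= set(frame.columns):
            raise ParameterError(
                f"divergence table needs columns {sorted(required)}"
            )
        return cls(
            {
                (r.species_a, r.species_b): r.T_myr
                for r in frame.itertuples()
            }
        )
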