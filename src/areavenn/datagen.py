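"""Random 3-set data generators used by the evaluation harness.

Two kinds of libraries are produced:

* **L1** (drawable data): the seven region areas of a randomly generated
  valid ellipse diagram -- centres uniform in [0, 100]^2, semi-axes uniform
  in [10, 50], rotations uniform in [0, pi) -- rejected until the topology
  is a proper 3-Venn arrangement, then scaled to a total of 1e5 and rounded
  to positive integers.  By construction an accurate ellipse diagram exists
  for every item, and the generating diagram is kept as a certificate.
* **L2** (random data): seven independent integers uniform on [1, 10000];
  whether an accurate diagram exists is unknown a priori.

Per-item seeds are derived from the library seed with
``numpy.random.SeedSequence(seed, spawn_key=(index,))``, a stable, platform
independent mixing function, so libraries are reproducible everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import numpy as np
import pandas as pd

from . import _core
from .diagram import REGION_LABELS, Quantities7, VennDiagram3

__all__ = [
    "DataLibrary",
    "random_drawable_item",
    "random_uniform_item",
    "generate_library",
    "read_library_csv",
]

#: total the L1 region areas are scaled to before integer rounding
L1_TOTAL = 100_000
#: bound on rejection attempts for one drawable item
MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class DataLibrary:
    """An ordered collection of generated 3-set data items."""

    items: List[Quantities7]
    kind: Literal["L1", "L2"]
    seed: int
    certificates: Optional[List[VennDiagram3]] = None

    def __len__(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{lab: q[lab] for lab in REGION_LABELS} for q in self.items]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def random_drawable_item(seed) -> Tuple[Quantities7, VennDiagram3]:
    """One drawable data item plus the diagram it was read off.

    Samples random ellipse triples until the topology is valid and every
    rounded region area is positive.
    """
    rng = np.random.default_rng(seed)
    for _ in range(MAX_ATTEMPTS):
        d = np.empty((3, 5))
        d[:, 0] = rng.uniform(0.0, 100.0, 3)
        d[:, 1] = rng.uniform(0.0, 100.0, 3)
        d[:, 2] = rng.uniform(10.0, 50.0, 3)
        d[:, 3] = rng.uniform(10.0, 50.0, 3)
        d[:, 4] = rng.uniform(0.0, np.pi, 3)
        areas, valid, consistent = _core._region_areas(d)
        if not (valid and consistent):
            continue
        scaled = areas * (L1_TOTAL / areas.sum())
        ints = np.rint(scaled).astype(int)
        if (ints <= 0).any():
            continue
        return Quantities7.from_array(ints), VennDiagram3.from_array(d)
    raise RuntimeError("rejection sampling failed to find a drawable item")


def random_uniform_item(seed) -> Quantities7:
    """Seven independent integers uniform on [1, 10000]."""
    rng = np.random.default_rng(seed)
    return Quantities7.from_array(rng.integers(1, 10_001, size=7))


def generate_library(n: int, kind: str, seed: int) -> DataLibrary:
    """Generate ``n`` items of the requested kind, reproducibly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind not in ("L1", "L2"):
        raise ValueError(f"unknown library kind {kind!r}")
    items: List[Quantities7] = []
    certs: List[VennDiagram3] = []
    for i in range(n):
        item_seed = np.random.SeedSequence(seed, spawn_key=(i,))
        if kind == "L1":
            q, cert = random_drawable_item(item_seed)
            items.append(q)
            certs.append(cert)
        else:
            items.append(random_uniform_item(item_seed))
    return DataLibrary(items, kind, seed, certs if kind == "L1" else None)


def read_library_csv(path: str | Path, kind: str = "L2", seed: int = -1) -> DataLibrary:
    """Load a library previously written with :meth:`DataLibrary.write_csv`."""
    df = pd.read_csv(path)
    items = [
        Quantities7({lab: row[lab] for lab in REGION_LABELS})
        for _, row in df.iterrows()
    ]
    return DataLibrary(items, kind, seed)  # type: ignore[arg-type]
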