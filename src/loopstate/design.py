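"""Hybridization designs for two-color loop experiments.

A loop design compares samples pairwise around a cycle instead of against a
common reference: each dual-color slide hybridizes one sample labelled Cy3
(arrow tail) against another labelled Cy5 (arrow head).  Walking log ratios
along the loop makes every sample's relative level estimable.  The default
design covers the twelve samples of a six-time-point perturbation series
(controls C1..C6 and treated UV1..UV6) with seventeen slides: a twelve-slide
closed loop, two dye-swap hybridizations, two technical replicates, and one
self–self mock slide used only for QC.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

ROLE_LOOP = "loop"
ROLE_DYE_SWAP = "dye_swap"
ROLE_TECHNICAL_REPLICATE = "technical_replicate"
ROLE_MOCK = "mock"
ROLES = (ROLE_LOOP, ROLE_DYE_SWAP, ROLE_TECHNICAL_REPLICATE, ROLE_MOCK)

CONTROL_SAMPLES = tuple(f"C{i}" for i in range(1, 7))
UV_SAMPLES = tuple(f"UV{i}" for i in range(1, 7))
ALL_SAMPLES = CONTROL_SAMPLES + UV_SAMPLES


@dataclass(frozen=True)
class Slide:
    """One dual-color slide: Cy3 (tail) vs Cy5 (head) sample, with a role."""

    slide_id: int
    cy3: str
    cy5: str
    role: str = ROLE_LOOP

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown slide role {self.role!r}; expected one of {ROLES}")
        if self.role == ROLE_MOCK and self.cy3 != self.cy5:
            raise ValueError("mock slide must hybridize the same sample in both channels")


class LoopDesign:
    """An ordered collection of slides over a set of samples."""

    def __init__(self, slides: Iterable[Slide]):
        self.slides: tuple[Slide, ...] = tuple(slides)
        if len({s.slide_id for s in self.slides}) != len(self.slides):
            raise ValueError("slide ids must be unique")

    def __len__(self) -> int:
        return len(self.slides)

    def __iter__(self):
        return iter(self.slides)

    def __getitem__(self, slide_id: int) -> Slide:
        for s in self.slides:
            if s.slide_id == slide_id:
                return s
        raise KeyError(slide_id)

    @property
    def samples(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.slides:
            seen.setdefault(s.cy3)
            seen.setdefault(s.cy5)
        return tuple(seen)

    def non_mock(self) -> "LoopDesign":
        return LoopDesign(s for s in self.slides if s.role != ROLE_MOCK)

    def graph(self, include_mock: bool = False) -> nx.MultiDiGraph:
        """Sample graph: nodes are samples, each slide a tail→head edge."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.samples)
        for s in self.slides:
            if s.role == ROLE_MOCK and not include_mock:
                continue
            g.add_edge(s.cy3, s.cy5, slide_id=s.slide_id, role=s.role)
        return g

    def is_connected(self) -> bool:
        g = self.graph(include_mock=False)
        return nx.is_connected(g.to_undirected(as_view=False))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": [s.slide_id for s in self.slides],
                "cy3_sample": [s.cy3 for s in self.slides],
                "cy5_sample": [s.cy5 for s in self.slides],
                "role": [s.role for s in self.slides],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LoopDesign":
        required = {"slide_id", "cy3_sample", "cy5_sample", "role"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"design sheet missing columns: {sorted(missing)}")
        return cls(
            Slide(int(r.slide_id), str(r.cy3_sample), str(r.cy5_sample), str(r.role))
            for r in frame.itertuples()
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LoopDesign":
        return cls.from_frame(pd.read_csv(path))


def default_loop_design() -> LoopDesign:
    """The seventeen-slide design over C1..C6 and UV1..UV6.

    Twelve loop slides traverse the cycle
    C1→UV1→C2→UV2→...→C6→UV6→C1 (tail = Cy3, head = Cy5).  Slides 11 and 15
    are technical replicates of two loop slides, slides 14 and 16 are dye
    swaps of two loop slides, and slide 17 is a C1/C1 mock, so that the
    published role-to-number map (11/15 technical, 14/16 swap, 17 mock) is
    respected.  Every sample appears in at least two non-mock slides and the
    non-mock slide graph is connected.
    """
    cycle: Sequence[str] = [
        "C1", "UV1", "C2", "UV2", "C3", "UV3",
        "C4", "UV4", "C5", "UV5", "C6", "UV6",
    ]
    edges = [(cycle[i], cycle[(i + 1) % 12]) for i in range(12)]
    slides = []
    # ids 1..10: first ten loop edges
    for k in range(10):
        slides.append(Slide(k + 1, edges[k][0], edges[k][1], ROLE_LOOP))
    # id 11: technical replicate of slide 1 (C1→UV1)
    slides.append(Slide(11, edges[0][0], edges[0][1], ROLE_TECHNICAL_REPLICATE))
    # ids 12, 13: remaining loop edges (C6→UV6, UV6→C1)
    slides.append(Slide(12, edges[10][0], edges[10][1], ROLE_LOOP))
    slides.append(Slide(13, edges[11][0], edges[11][1], ROLE_LOOP))
    # id 14: dye swap of slide 2 (UV1→C2 becomes C2→UV1)
    slides.append(Slide(14, edges[1][1], edges[1][0], ROLE_DYE_SWAP))
    # id 15: technical replicate of slide 7 (C4→UV4)
    slides.append(Slide(15, edges[6][0], edges[6][1], ROLE_TECHNICAL_REPLICATE))
    # id 16: dye swap of slide 8 (UV4→C5 becomes C5→UV4)
    slides.append(Slide(16, edges[7][1], edges[7][0], ROLE_DYE_SWAP))
    # id 17: mock self-self hybridization
    slides.append(Slide(17, "C1", "C1", ROLE_MOCK))
    return LoopDesign(slides)
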