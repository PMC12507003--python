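"""Geometry of the artificial burrow: nine boxes joined by twelve pipes.

The housing system is a 3x3 array of boxes connected to orthogonal
neighbors by pipes, modelled as a 5x5 grid in which each box or pipe
occupies one square.  Boxes sit at even (row, col) positions, the pipe
joining two adjacent boxes occupies the cell between them, and the four
remaining diagonal cells are void.  Each pipe carries two ring-antenna
RFID readers, one at either end, so a reader identifies both a pipe cell
and the box at that end of the pipe.

Cells are addressed either as ``(row, col)`` pairs or as flat integer
codes ``row * 5 + col``; the sentinel :data:`UNKNOWN` (-1) marks ticks at
which an individual could not be located.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

GRID_SIZE = 5
N_CELLS = GRID_SIZE * GRID_SIZE

#: Sentinel cell code for "location not available".
UNKNOWN = -1

BOX = "box"
PIPE = "pipe"
VOID = "void"


class LayoutError(ValueError):
    """Raised when a burrow layout description is invalid."""


def cell_code(row: int, col: int) -> int:
    """Flat integer code of grid cell ``(row, col)``."""
    if not (0 <= row < GRID_SIZE and 0 <= col < GRID_SIZE):
        raise LayoutError(f"cell ({row}, {col}) outside the {GRID_SIZE}x{GRID_SIZE} grid")
    return row * GRID_SIZE + col


def cell_coords(code: int) -> tuple[int, int]:
    """Inverse of :func:`cell_code`."""
    if not (0 <= code < N_CELLS):
        raise LayoutError(f"cell code {code} outside the grid")
    return divmod(code, GRID_SIZE)


def cell_kind(row: int, col: int) -> str:
    """Kind of a 5x5 cell: box (even, even), void (odd, odd), else pipe."""
    if not (0 <= row < GRID_SIZE and 0 <= col < GRID_SIZE):
        raise LayoutError(f"cell ({row}, {col}) outside the grid")
    if row % 2 == 0 and col % 2 == 0:
        return BOX
    if row % 2 == 1 and col % 2 == 1:
        return VOID
    return PIPE


@dataclass(frozen=True)
class Reader:
    """An RFID ring antenna at one end of a pipe.

    Attributes
    ----------
    id : str
        Reader identifier as it appears in detection logs.
    pipe : int
        Cell code of the pipe the antenna is mounted on.
    box : int
        Cell code of the box at this reader's end of the pipe.
    """

    id: str
    pipe: int
    box: int


@dataclass
class GridLayout:
    """Validated burrow geometry with reader placement.

    Use :func:`build_layout` or :func:`default_layout` to construct one.
    """

    readers: dict[str, Reader]
    box_codes: tuple[int, ...]
    pipe_codes: tuple[int, ...]
    void_codes: tuple[int, ...]
    #: cell code -> orthogonally neighboring non-void cell codes (symmetric)
    adjacency: dict[int, tuple[int, ...]] = field(repr=False)
    _pipe_between: dict[tuple[int, int], int] = field(repr=False)
    _reader_at: dict[tuple[int, int], str] = field(repr=False)

    # -- queries -----------------------------------------------------------
    def is_box(self, code: int) -> bool:
        return code in self._box_set

    def is_pipe(self, code: int) -> bool:
        return code in self._pipe_set

    def __post_init__(self) -> None:
        self._box_set = frozenset(self.box_codes)
        self._pipe_set = frozenset(self.pipe_codes)

    def pipe_between(self, box_a: int, box_b: int) -> int | None:
        """Pipe cell joining two boxes, or None if they are not neighbors."""
        return self._pipe_between.get((min(box_a, box_b), max(box_a, box_b)))

    def reader_at(self, pipe: int, box: int) -> str:
        """Id of the reader on ``pipe`` at the end facing ``box``."""
        try:
            return self._reader_at[(pipe, box)]
        except KeyError:
            raise LayoutError(f"no reader on pipe {pipe} at box {box}") from None

    def common_box(self, pipe_a: int, pipe_b: int) -> int | None:
        """The unique box adjacent to both pipes, or None.

        Two distinct pipes share at most one box on this grid (each
        adjacent box pair is joined by exactly one pipe).
        """
        shared = set(self.adjacency[pipe_a]) & set(self.adjacency[pipe_b])
        shared &= self._box_set
        if len(shared) == 1:
            return next(iter(shared))
        return None

    def box_neighbors(self, box: int) -> tuple[tuple[int, int], ...]:
        """``(pipe, box)`` pairs reachable from ``box`` through one pipe."""
        out = []
        for pipe in self.adjacency[box]:
            for other in self.adjacency[pipe]:
                if other != box and other in self._box_set:
                    out.append((pipe, other))
        return tuple(sorted(out, key=lambda t: t[1]))

    def pipes_adjacent_to(self, box: int) -> tuple[int, ...]:
        return tuple(c for c in self.adjacency[box] if c in self._pipe_set)


def default_layout_spec() -> dict:
    """Canonical layout description: 9 boxes, 12 pipes, 24 readers.

    Reader ids are ``R01`` .. ``R24``, assigned in (pipe cell, end box)
    sort order.
    """
    boxes = [(r, c) for r in (0, 2, 4) for c in (0, 2, 4)]
    pipes = []
    for r, c in boxes:
        if c + 2 < GRID_SIZE:
            pipes.append((r, c + 1))
        if r + 2 < GRID_SIZE:
            pipes.append((r + 1, c))
    pipes.sort()
    readers: dict[str, dict] = {}
    ends = []
    for pr, pc in pipes:
        if pr % 2 == 0:  # horizontal pipe
            ends.append(((pr, pc), (pr, pc - 1)))
            ends.append(((pr, pc), (pr, pc + 1)))
        else:  # vertical pipe
            ends.append(((pr, pc), (pr - 1, pc)))
            ends.append(((pr, pc), (pr + 1, pc)))
    for i, (pipe, box) in enumerate(sorted(ends), start=1):
        readers[f"R{i:02d}"] = {"pipe": list(pipe), "box": list(box)}
    return {
        "boxes": [list(b) for b in boxes],
        "pipes": [list(p) for p in pipes],
        "readers": readers,
    }


def build_layout(spec: Mapping) -> GridLayout:
    """Validate a layout description and build a :class:`GridLayout`.

    ``spec`` must contain ``boxes`` (9 cells in a 3x3 arrangement),
    ``pipes`` (12 cells, one between every adjacent box pair) and
    ``readers`` (24 entries mapping id -> {pipe, box}).
    """
    try:
        boxes = [cell_code(r, c) for r, c in spec["boxes"]]
        pipes = [cell_code(r, c) for r, c in spec["pipes"]]
        reader_spec = dict(spec["readers"])
    except (KeyError, TypeError, ValueError) as exc:
        raise LayoutError(f"malformed layout spec: {exc}") from exc

    expected_boxes = sorted(cell_code(r, c) for r in (0, 2, 4) for c in (0, 2, 4))
    if sorted(boxes) != expected_boxes:
        raise LayoutError("boxes must occupy the nine (even, even) grid cells")
    for code in pipes:
        r, c = cell_coords(code)
        if cell_kind(r, c) != PIPE:
            raise LayoutError(f"pipe at ({r}, {c}) is not a pipe-kind cell")
    if len(set(pipes)) != len(pipes):
        raise LayoutError("duplicate pipe cells")

    # adjacency over non-void cells
    box_set = set(boxes)
    pipe_set = set(pipes)
    occupied = box_set | pipe_set
    adjacency: dict[int, tuple[int, ...]] = {}
    for code in sorted(occupied):
        r, c = cell_coords(code)
        nbrs = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < GRID_SIZE and 0 <= cc < GRID_SIZE:
                ncode = cell_code(rr, cc)
                if ncode in occupied:
                    nbrs.append(ncode)
        adjacency[code] = tuple(nbrs)

    # every adjacent box pair must be joined by a pipe
    pipe_between: dict[tuple[int, int], int] = {}
    for pipe in pipes:
        flank = [b for b in adjacency[pipe] if b in box_set]
        if len(flank) != 2:
            raise LayoutError(f"pipe {cell_coords(pipe)} does not join two boxes")
        a, b = sorted(flank)
        pipe_between[(a, b)] = pipe
    for a in boxes:
        ra, ca = cell_coords(a)
        for dr, dc in ((0, 2), (2, 0)):
            rb, cb = ra + dr, ca + dc
            if rb < GRID_SIZE and cb < GRID_SIZE:
                b = cell_code(rb, cb)
                if (min(a, b), max(a, b)) not in pipe_between:
                    raise LayoutError(
                        f"missing pipe between boxes {cell_coords(a)} and {(rb, cb)}"
                    )

    # readers
    readers: dict[str, Reader] = {}
    reader_at: dict[tuple[int, int], str] = {}
    per_pipe: dict[int, list[int]] = {p: [] for p in pipes}
    for rid, entry in reader_spec.items():
        try:
            pipe = cell_code(*entry["pipe"])
            box = cell_code(*entry["box"])
        except (KeyError, TypeError, ValueError) as exc:
            raise LayoutError(f"malformed reader {rid!r}: {exc}") from exc
        if pipe not in pipe_set:
            raise LayoutError(f"reader {rid!r} assigned to non-pipe cell {cell_coords(pipe)}")
        if box not in box_set or box not in adjacency[pipe]:
            raise LayoutError(f"reader {rid!r}: box {cell_coords(box)} is not an end of its pipe")
        if (pipe, box) in reader_at:
            raise LayoutError(f"two readers at the same pipe end {cell_coords(pipe)}/{cell_coords(box)}")
        readers[str(rid)] = Reader(str(rid), pipe, box)
        reader_at[(pipe, box)] = str(rid)
        per_pipe[pipe].append(box)
    for pipe, ends in per_pipe.items():
        if len(ends) != 2:
            raise LayoutError(f"pipe {cell_coords(pipe)} must carry exactly two readers")

    void = tuple(
        cell_code(r, c)
        for r in range(GRID_SIZE)
        for c in range(GRID_SIZE)
        if cell_kind(r, c) == VOID
    )
    return GridLayout(
        readers=readers,
        box_codes=tuple(sorted(boxes)),
        pipe_codes=tuple(sorted(pipes)),
        void_codes=void,
        adjacency=adjacency,
        _pipe_between=pipe_between,
        _reader_at=reader_at,
    )


def default_layout() -> GridLayout:
    """The canonical 3x3-box burrow with 24 readers."""
    return build_layout(default_layout_spec())
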