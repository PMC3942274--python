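"""Gene-order synteny: signed circular permutations, conserved adjacencies,
synteny blocks and breakpoint counts.

A genome's gene order is a cyclic list of signed gene symbols (the sign is
the strand). Rearrangement between two genomes is quantified as the signed
circular breakpoint count: the number of gene adjacencies of one order,
restricted to the genes the two genomes share, that are absent from the
other order (an adjacency x->y survives as -y->-x on the opposite strand).
This operationalizes "recombination/rearrangement events"; maximal runs of
conserved adjacencies are the synteny blocks, with isolated conserved pairs
reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import GeneAnnotation

SignedGene = tuple[str, int]  # (name, +1 | -1)


def _neg(g: SignedGene) -> SignedGene:
    return (g[0], -g[1])


@dataclass(frozen=True)
class GeneOrder:
    """A signed circular gene order; cyclic rotations are equal orders."""

    genome_id: str
    order: tuple[SignedGene, ...]

    def __post_init__(self) -> None:
        names = [g[0] for g in self.order]
        if len(names) != len(set(names)):
            raise ValueError("gene symbols must be unique within an order")
        if any(g[1] not in (1, -1) for g in self.order):
            raise ValueError("signs must be +1 or -1")

    @property
    def names(self) -> set[str]:
        return {g[0] for g in self.order}

    def induced(self, shared: set[str]) -> "GeneOrder":
        """Subpermutation restricted to ``shared`` genes, order preserved."""
        return GeneOrder(
            self.genome_id, tuple(g for g in self.order if g[0] in shared)
        )

    def cyclic_equal(self, other: "GeneOrder") -> bool:
        """Equality up to rotation (and global flip: reversal + sign change)."""
        n = len(self.order)
        if n != len(other.order):
            return False
        if n == 0:
            return True
        flipped = tuple(_neg(g) for g in reversed(other.order))
        for cand in (other.order, flipped):
            for r in range(n):
                if self.order == cand[r:] + cand[:r]:
                    return True
        return False

    def adjacencies(self) -> list[tuple[SignedGene, SignedGene]]:
        n = len(self.order)
        return [(self.order[i], self.order[(i + 1) % n]) for i in range(n)]


@dataclass
class SyntenyBlock:
    genes: tuple[SignedGene, ...]  # signs as they appear in the first order
    orientation: str  # same | inverted
    a_span: tuple[int, int] | None = None
    b_span: tuple[int, int] | None = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class RearrangementReport:
    common_genes: int
    conserved_pairs: list[tuple[SignedGene, SignedGene]]
    blocks: list[SyntenyBlock]
    breakpoints: int
    events_estimate: int


def gene_order_from_annotations(
    annotations: list[GeneAnnotation],
    genome_length: int | None = None,
    genome_id: str = "genome",
) -> GeneOrder:
    """Cyclic order of genes by start coordinate, signed by strand.

    Gene ids that occur multiple times are disambiguated deterministically by
    coordinate order with ``-1``, ``-2`` suffixes.
    """
    ordered = sorted(annotations, key=lambda a: (a.start, a.gene_id))
    counts: dict[str, int] = {}
    for ann in ordered:
        counts[ann.gene_id] = counts.get(ann.gene_id, 0) + 1
    seen: dict[str, int] = {}
    symbols: list[SignedGene] = []
    for ann in ordered:
        if counts[ann.gene_id] > 1:
            seen[ann.gene_id] = seen.get(ann.gene_id, 0) + 1
            name = f"{ann.gene_id}-{seen[ann.gene_id]}"
        else:
            name = ann.gene_id
        symbols.append((name, 1 if ann.strand == "+" else -1))
    return GeneOrder(genome_id=genome_id, order=tuple(symbols))


def _adjacency_conserved(
    x: SignedGene, y: SignedGene, b_pos: dict[str, int], b_order: tuple[SignedGene, ...]
) -> bool:
    """Does the adjacency x->y of order A survive in order B (possibly on
    the opposite strand, where it reads -y->-x)?"""
    n = len(b_order)
    px = b_pos[x[0]]
    bx = b_order[px]
    if bx[1] == x[1]:
        succ = b_order[(px + 1) % n]
        return succ == y
    pred = b_order[(px - 1) % n]
    return pred == _neg(y)


def _conservation_flags(a: GeneOrder, b: GeneOrder) -> tuple[GeneOrder, GeneOrder, list[bool]]:
    shared = a.names & b.names
    if len(shared) < 2:
        raise ValueError("need at least 2 shared genes")
    ia = a.induced(shared)
    ib = b.induced(shared)
    b_pos = {g[0]: i for i, g in enumerate(ib.order)}
    flags = [
        _adjacency_conserved(x, y, b_pos, ib.order) for x, y in ia.adjacencies()
    ]
    return ia, ib, flags


def breakpoint_count(a: GeneOrder, b: GeneOrder) -> int:
    """Signed circular breakpoint distance on the induced subpermutation of
    shared genes: adjacencies of A absent from B. Symmetric in its
    arguments; 0 for equal orders."""
    _, _, flags = _conservation_flags(a, b)
    return sum(1 for ok in flags if not ok)


def synteny_blocks(
    a: GeneOrder,
    b: GeneOrder,
    a_annotations: dict[str, GeneAnnotation] | None = None,
    b_annotations: dict[str, GeneAnnotation] | None = None,
) -> list[SyntenyBlock]:
    """Maximal runs of shared genes whose internal adjacencies are conserved
    in both orders (whole-block inversion allowed). Blocks have >= 2 genes;
    bp spans are attached when annotation maps (symbol -> annotation) are
    supplied."""
    ia, ib, flags = _conservation_flags(a, b)
    n = len(ia.order)
    if all(flags):
        runs = [list(range(n))]
    else:
        # break the circle at every broken adjacency
        runs = []
        breaks = [i for i, ok in enumerate(flags) if not ok]
        start = (breaks[-1] + 1) % n
        run = [start]
        i = start
        for _ in range(n - 1):
            j = (i + 1) % n
            if flags[i]:
                run.append(j)
            else:
                runs.append(run)
                run = [j]
            i = j
        runs.append(run)

    b_pos = {g[0]: i for i, g in enumerate(ib.order)}
    blocks = []
    for run in runs:
        if len(run) < 2:
            continue
        genes = tuple(ia.order[i] for i in run)
        first = genes[0]
        orientation = (
            "same" if ib.order[b_pos[first[0]]][1] == first[1] else "inverted"
        )
        blocks.append(
            SyntenyBlock(
                genes=genes,
                orientation=orientation,
                a_span=_span(genes, a_annotations),
                b_span=_span(genes, b_annotations),
            )
        )
    return blocks


def _span(genes, annotations) -> tuple[int, int] | None:
    if annotations is None:
        return None
    members = [annotations[g[0]] for g in genes if g[0] in annotations]
    if not members:
        return None
    return (min(m.start for m in members), max(m.end for m in members))


def conserved_pairs(
    a: GeneOrder, b: GeneOrder
) -> list[tuple[SignedGene, SignedGene]]:
    """Orientation-consistent adjacencies conserved in both cyclic orders
    that are NOT part of a larger conserved run -- i.e. the isolated gene
    pairs, reported separately from multi-gene blocks."""
    return [
        (blk.genes[0], blk.genes[1])
        for blk in synteny_blocks(a, b)
        if blk.n_genes == 2
    ]


def block_genome_fraction(
    blocks: list[SyntenyBlock], genome_length: int
) -> tuple[int, float]:
    """Total bp of (non-overlapping) block spans on genome a, and the
    fraction of the genome they cover."""
    spans = sorted(
        (blk.a_span for blk in blocks if blk.a_span is not None)
    )
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping block spans ({s1},{e1}) and ({s2},{e2})")
    total = sum(e - s for s, e in spans)
    return total, total / genome_length


def compare_gene_orders(
    a: GeneOrder,
    b: GeneOrder,
    a_annotations: dict[str, GeneAnnotation] | None = None,
    b_annotations: dict[str, GeneAnnotation] | None = None,
) -> RearrangementReport:
    """Full pairwise rearrangement report: shared genes, isolated conserved
    pairs, synteny blocks, and the breakpoint count (reported as the
    rearrangement-event estimate)."""
    shared = a.names & b.names
    blocks = synteny_blocks(a, b, a_annotations, b_annotations)
    bp = breakpoint_count(a, b)
    pairs = [
        (blk.genes[0], blk.genes[1]) for blk in blocks if blk.n_genes == 2
    ]
    return RearrangementReport(
        common_genes=len(shared),
        conserved_pairs=pairs,
        blocks=[blk for blk in blocks if blk.n_genes > 2],
        breakpoints=bp,
        events_estimate=bp,
    )


def write_synteny_svg(path, orders: list[GeneOrder]) -> None:
    """Minimal gene-strip rendering: one horizontal strip per genome, boxes
    in cyclic order, minus-strand genes drawn below the line."""
    box_w, box_h, row_h, pad = 60, 16, 60, 10
    width = pad * 2 + box_w * max((len(o.order) for o in orders), default=1)
    height = row_h * len(orders) + pad
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">'
    ]
    for r, order in enumerate(orders):
        y = pad + r * row_h
        lines.append(
            f'<text x="{pad}" y="{y}" font-size="12">{order.genome_id}</text>'
        )
        for i, (name, sign) in enumerate(order.order):
            x = pad + i * box_w
            yy = y + 6 if sign > 0 else y + 6 + box_h
            colour = "#7fb3d5" if sign > 0 else "#f5b7b1"
            lines.append(
                f'<rect x="{x}" y="{yy}" width="{box_w - 4}" height="{box_h}" '
                f'fill="{colour}" stroke="black"/>'
            )
            lines.append(
                f'<text x="{x + 2}" y="{yy + 12}" font-size="9">{name}</text>'
            )
    lines.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
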