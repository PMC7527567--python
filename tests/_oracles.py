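"""Independent brute-force oracles used only by the test suite.

Everything here is written with explicit per-cell loops and BFS so it
shares no code path with the package implementation.
"""

from collections import deque
from math import log, sqrt

ORTH = [(-1, 0), (1, 0), (0, -1), (0, 1)]
DIAG = [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def bfs_patches(grid, connectivity=8):
    """List of patches; each patch is a list of (r, c) same-class cells."""
    nrows, ncols = len(grid), len(grid[0])
    seen = [[False] * ncols for _ in range(nrows)]
    nbrs = ORTH + (DIAG if connectivity == 8 else [])
    patches = []
    for r in range(nrows):
        for c in range(ncols):
            if seen[r][c] or grid[r][c] is None:
                continue
            code = grid[r][c]
            q = deque([(r, c)])
            seen[r][c] = True
            cells = []
            while q:
                rr, cc = q.popleft()
                cells.append((rr, cc))
                for dr, dc in nbrs:
                    r2, c2 = rr + dr, cc + dc
                    if (0 <= r2 < nrows and 0 <= c2 < ncols
                            and not seen[r2][c2] and grid[r2][c2] == code):
                        seen[r2][c2] = True
                        q.append((r2, c2))
            patches.append((code, cells))
    return patches


def patch_perimeter(grid, cells, cell_size):
    """Exposed sides of one patch, meters (unlike class, None, or edge)."""
    nrows, ncols = len(grid), len(grid[0])
    code = grid[cells[0][0]][cells[0][1]]
    sides = 0
    for r, c in cells:
        for dr, dc in ORTH:
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < nrows and 0 <= c2 < ncols):
                sides += 1
            elif grid[r2][c2] != code:
                sides += 1
    return sides * cell_size


def patch_contiguity(cells):
    """Mean 3x3 template value over the patch, rescaled to [0, 1]."""
    cellset = set(cells)
    total = 0.0
    for r, c in cells:
        v = 1.0
        for dr, dc in ORTH:
            if (r + dr, c + dc) in cellset:
                v += 2.0
        for dr, dc in DIAG:
            if (r + dr, c + dc) in cellset:
                v += 1.0
        total += v
    return (total / len(cells) - 1.0) / 12.0


def landscape_metrics(grid, cell_size):
    """All seven landscape-level metrics by direct enumeration."""
    nrows, ncols = len(grid), len(grid[0])
    cells = [(r, c) for r in range(nrows) for c in range(ncols)
             if grid[r][c] is not None]
    A_m2 = len(cells) * cell_size * cell_size
    A_ha = A_m2 / 1e4

    unlike = 0
    boundary = 0
    for r, c in cells:
        for dr, dc in ORTH:
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < nrows and 0 <= c2 < ncols) or grid[r2][c2] is None:
                boundary += 1
            elif grid[r2][c2] != grid[r][c]:
                unlike += 1
    unlike_m = (unlike / 2) * cell_size   # each internal side visited twice
    boundary_m = boundary * cell_size

    patches = bfs_patches(grid, 8)
    counts = {}
    for r, c in cells:
        counts[grid[r][c]] = counts.get(grid[r][c], 0) + 1
    n = len(counts)
    p = {k: v / len(cells) for k, v in counts.items()}

    shdi = -sum(pi * log(pi) for pi in p.values())
    shei = shdi / log(n) if n > 1 else float("nan")

    # contagion from double-counted 4-adjacencies
    if n > 1:
        g = {}
        for r, c in cells:
            for dr, dc in ORTH:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nrows and 0 <= c2 < ncols and grid[r2][c2] is not None:
                    key = (grid[r][c], grid[r2][c2])
                    g[key] = g.get(key, 0) + 1
        acc = 0.0
        for i in counts:
            gi = sum(g.get((i, k), 0) for k in counts)
            for k in counts:
                q = p[i] * g.get((i, k), 0) / gi if gi else 0.0
                if q > 0:
                    acc += q * log(q)
        contag = 100.0 * (1.0 + acc / (2.0 * log(n)))
    else:
        contag = float("nan")

    return {
        "ED": unlike_m / A_ha,
        "PD": len(patches) / (A_ha / 100.0),
        "LSI": 0.25 * (unlike_m + boundary_m) / sqrt(A_m2),
        "LPI": 100.0 * max(len(cs) for _, cs in patches) * cell_size**2 / A_m2,
        "CONTAG": contag,
        "SHDI": shdi,
        "SHEI": shei,
    }


def class_metrics(grid, code, cell_size):
    """Class-level PD, LSI, LPI, CONTIG_AM by direct enumeration."""
    nrows, ncols = len(grid), len(grid[0])
    cells = [(r, c) for r in range(nrows) for c in range(ncols)
             if grid[r][c] is not None]
    A_m2 = len(cells) * cell_size * cell_size
    A_ha = A_m2 / 1e4
    patches = [(cd, cs) for cd, cs in bfs_patches(grid, 8) if cd == code]
    A_cls = sum(len(cs) for _, cs in patches) * cell_size**2
    E_cls = sum(patch_perimeter(grid, cs, cell_size) for _, cs in patches)
    contig_am = sum(
        len(cs) * cell_size**2 * patch_contiguity(cs) for _, cs in patches
    ) / A_cls
    return {
        "PD": len(patches) / (A_ha / 100.0),
        "LSI": 0.25 * E_cls / sqrt(A_cls),
        "LPI": 100.0 * max(len(cs) for _, cs in patches) * cell_size**2 / A_m2,
        "CONTIG_AM": contig_am,
    }


def transition_counts(g0, g1, codes):
    """Brute-force per-cell joint counts between two grids."""
    t = {(i, j): 0 for i in codes for j in codes}
    for r in range(len(g0)):
        for c in range(len(g0[0])):
            if g0[r][c] is not None:
                t[(g0[r][c], g1[r][c])] += 1
    return t
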