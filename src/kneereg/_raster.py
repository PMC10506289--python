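"""Low-level numba kernels: triangle rasterization and boundary tracing.

These run once per cost evaluation inside the optimizer loop, so they are
compiled with numba rather than written against scikit-image's per-polygon
API. Coordinates follow the package convention: x = column, y = row, pixel
centers at integer coordinates.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def fill_triangles(mask, tri, cull=0):
    """Rasterize filled triangles into a boolean raster (logical OR).

    Parameters
    ----------
    mask : (H, W) bool array, modified in place.
    tri : (F, 3, 2) float array of (x, y) vertex coordinates in the local
        pixel frame of ``mask``.
    cull : 0 rasterizes every triangle; +1 / -1 rasterize only triangles of
        that signed-area orientation. For a closed orientable surface the
        front-facing triangles alone cover the whole silhouette, so culling
        halves the work without changing the result.

    A pixel is set when its center lies inside or on the edge of any
    triangle (inclusive edge test, so shared edges between adjacent
    triangles never leave seams).
    """
    H, W = mask.shape
    for f in range(tri.shape[0]):
        x0 = tri[f, 0, 0]
        y0 = tri[f, 0, 1]
        x1 = tri[f, 1, 0]
        y1 = tri[f, 1, 1]
        x2 = tri[f, 2, 0]
        y2 = tri[f, 2, 1]
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if area == 0.0:
            continue
        if cull > 0 and area < 0.0:
            continue
        if cull < 0 and area > 0.0:
            continue
        s = 1.0 if area > 0.0 else -1.0
        xmn = min(x0, min(x1, x2))
        xmx = max(x0, max(x1, x2))
        ymn = min(y0, min(y1, y2))
        ymx = max(y0, max(y1, y2))
        ix0 = int(np.ceil(xmn - 1e-9))
        ix1 = int(np.floor(xmx + 1e-9))
        iy0 = int(np.ceil(ymn - 1e-9))
        iy1 = int(np.floor(ymx + 1e-9))
        if ix0 < 0:
            ix0 = 0
        if iy0 < 0:
            iy0 = 0
        if ix1 > W - 1:
            ix1 = W - 1
        if iy1 > H - 1:
            iy1 = H - 1
        eps = 1e-9 * (abs(area) + 1.0)
        for py in range(iy0, iy1 + 1):
            for px in range(ix0, ix1 + 1):
                if mask[py, px]:
                    continue
                w0 = s * ((x1 - x0) * (py - y0) - (px - x0) * (y1 - y0))
                if w0 < -eps:
                    continue
                w1 = s * ((x2 - x1) * (py - y1) - (px - x1) * (y2 - y1))
                if w1 < -eps:
                    continue
                w2 = s * ((x0 - x2) * (py - y2) - (px - x2) * (y0 - y2))
                if w2 < -eps:
                    continue
                mask[py, px] = True


@njit(cache=True)
def _trace(mask, out):
    """Moore-neighbor boundary trace with Jacob's stopping criterion.

    Writes (y, x) boundary pixels in order into ``out``; returns the number
    written, 0 for an empty mask, or -1 if ``out`` is too small.
    """
    H, W = mask.shape
    sy = -1
    sx = -1
    for y in range(H):
        for x in range(W):
            if mask[y, x]:
                sy = y
                sx = x
                break
        if sy >= 0:
            break
    if sy < 0:
        return 0
    cap = out.shape[0]
    # clockwise Moore neighborhood starting at West
    dy8 = (0, -1, -1, -1, 0, 1, 1, 1)
    dx8 = (-1, -1, 0, 1, 1, 1, 0, -1)
    cy = sy
    cx = sx
    b = 0  # backtrack index: neighbor we entered from (W for the start pixel)
    n = 0
    out[n, 0] = cy
    out[n, 1] = cx
    n += 1
    start_b = b
    while True:
        nxt = -1
        for k in range(1, 9):
            j = (b + k) % 8
            ny = cy + dy8[j]
            nx = cx + dx8[j]
            if 0 <= ny < H and 0 <= nx < W and mask[ny, nx]:
                nxt = j
                break
        if nxt == -1:
            return n  # isolated single pixel
        # background cell checked just before entering the new pixel
        prev = (nxt + 7) % 8
        py = cy + dy8[prev]
        px = cx + dx8[prev]
        cy = cy + dy8[nxt]
        cx = cx + dx8[nxt]
        vy = py - cy
        vx = px - cx
        for m in range(8):
            if dy8[m] == vy and dx8[m] == vx:
                b = m
                break
        if cy == sy and cx == sx and b == start_b:
            return n
        if n >= cap:
            return -1
        out[n, 0] = cy
        out[n, 1] = cx
        n += 1


def trace_outer_boundary(mask):
    """Ordered (y, x) outer-boundary pixels of the largest blob in ``mask``.

    Returns an (n, 2) int64 array. The caller is expected to pass a mask
    with a single connected component.
    """
    H, W = mask.shape
    buf = np.empty((8 * (H + W) + 64, 2), np.int64)
    n = _trace(mask, buf)
    if n == -1:
        buf = np.empty((4 * H * W + 8, 2), np.int64)
        n = _trace(mask, buf)
    return buf[:n].copy()


@njit(cache=True)
def _label_filled(mask):
    """Label the hole-filled blobs of ``mask``; return (labels, best_label).

    Exterior background is what a border flood fill (4-connectivity)
    reaches; everything else is foreground-with-holes-filled. Blobs are
    labeled 1.. by 8-connected flood fill; ``best_label`` is the largest.
    """
    H, W = mask.shape
    lab = np.zeros((H, W), np.int32)  # 0 unvisited, -1 exterior, >0 blob id
    stack = np.empty(H * W, np.int32)
    top = 0
    for x in range(W):
        for y in (0, H - 1):
            if not mask[y, x] and lab[y, x] == 0:
                lab[y, x] = -1
                stack[top] = y * W + x
                top += 1
    for y in range(H):
        for x in (0, W - 1):
            if not mask[y, x] and lab[y, x] == 0:
                lab[y, x] = -1
                stack[top] = y * W + x
                top += 1
    while top > 0:
        top -= 1
        p = stack[top]
        y = p // W
        x = p % W
        if y > 0 and not mask[y - 1, x] and lab[y - 1, x] == 0:
            lab[y - 1, x] = -1
            stack[top] = p - W
            top += 1
        if y < H - 1 and not mask[y + 1, x] and lab[y + 1, x] == 0:
            lab[y + 1, x] = -1
            stack[top] = p + W
            top += 1
        if x > 0 and not mask[y, x - 1] and lab[y, x - 1] == 0:
            lab[y, x - 1] = -1
            stack[top] = p - 1
            top += 1
        if x < W - 1 and not mask[y, x + 1] and lab[y, x + 1] == 0:
            lab[y, x + 1] = -1
            stack[top] = p + 1
            top += 1
    best_label = 0
    best_count = 0
    next_label = 0
    for sy in range(H):
        for sx in range(W):
            if lab[sy, sx] != 0:
                continue
            next_label += 1
            lab[sy, sx] = next_label
            stack[0] = sy * W + sx
            top = 1
            count = 0
            while top > 0:
                top -= 1
                p = stack[top]
                count += 1
                y = p // W
                x = p % W
                y0 = y - 1 if y > 0 else 0
                y1 = y + 1 if y < H - 1 else H - 1
                x0 = x - 1 if x > 0 else 0
                x1 = x + 1 if x < W - 1 else W - 1
                for ny in range(y0, y1 + 1):
                    for nx in range(x0, x1 + 1):
                        if lab[ny, nx] == 0:
                            lab[ny, nx] = next_label
                            stack[top] = ny * W + nx
                            top += 1
            if count > best_count:
                best_count = count
                best_label = next_label
    return lab, best_label, best_count


def clean_mask(mask):
    """Fill interior holes and keep only the largest connected blob.

    Returns (cleaned bool array, pixel count of the kept blob).
    """
    lab, best, count = _label_filled(mask)
    return lab == best, count


@njit(cache=True)
def project_mesh_tris(verts, faces, R, c, tr, src, o, a1, a2, nrm, spacing):
    """Pose + perspective projection + face gather fused in one pass.

    Applies v' = R (v - c) + c + tr, projects every vertex from the point
    source onto the detector plane, and gathers the per-face triangles in
    detector pixel coordinates. Returns
    (tris (F, 3, 2), xmn, xmx, ymn, ymx, ok); ok is False when any posed
    vertex is not strictly between the source and the detector plane.
    """
    N = verts.shape[0]
    pts = np.empty((N, 2))
    num = (
        (o[0] - src[0]) * nrm[0]
        + (o[1] - src[1]) * nrm[1]
        + (o[2] - src[2]) * nrm[2]
    )
    ok = True
    xmn = 1e300
    xmx = -1e300
    ymn = 1e300
    ymx = -1e300
    for i in range(N):
        ux = verts[i, 0] - c[0]
        uy = verts[i, 1] - c[1]
        uz = verts[i, 2] - c[2]
        px = R[0, 0] * ux + R[0, 1] * uy + R[0, 2] * uz + c[0] + tr[0]
        py = R[1, 0] * ux + R[1, 1] * uy + R[1, 2] * uz + c[1] + tr[1]
        pz = R[2, 0] * ux + R[2, 1] * uy + R[2, 2] * uz + c[2] + tr[2]
        dpn = (
            (px - src[0]) * nrm[0]
            + (py - src[1]) * nrm[1]
            + (pz - src[2]) * nrm[2]
        )
        frac = dpn / num
        if frac <= 1e-9 or frac >= 1.0 - 1e-9:
            ok = False
            pts[i, 0] = 0.0
            pts[i, 1] = 0.0
            continue
        t = num / dpn
        qx = src[0] + t * (px - src[0]) - o[0]
        qy = src[1] + t * (py - src[1]) - o[1]
        qz = src[2] + t * (pz - src[2]) - o[2]
        x = (qx * a1[0] + qy * a1[1] + qz * a1[2]) / spacing
        y = (qx * a2[0] + qy * a2[1] + qz * a2[2]) / spacing
        pts[i, 0] = x
        pts[i, 1] = y
        if x < xmn:
            xmn = x
        if x > xmx:
            xmx = x
        if y < ymn:
            ymn = y
        if y > ymx:
            ymx = y
    F = faces.shape[0]
    tris = np.empty((F, 3, 2))
    for f in range(F):
        for k in range(3):
            tris[f, k, 0] = pts[faces[f, k], 0]
            tris[f, k, 1] = pts[faces[f, k], 1]
    return tris, xmn, xmx, ymn, ymx, ok


def warmup():
    """Trigger JIT compilation on a tiny input (used by tests and the CLI)."""
    m = np.zeros((8, 8), np.bool_)
    tri = np.array([[[1.0, 1.0], [6.0, 1.0], [3.0, 6.0]]])
    fill_triangles(m, tri)
    clean_mask(m)
    trace_outer_boundary(m)
    project_mesh_tris(
        np.array([[0.0, 0.0, 0.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        np.array([[0, 1, 2], [0, 1, 3]], np.int64),
        np.eye(3),
        np.zeros(3),
        np.zeros(3),
        np.array([0.0, 0.0, 100.0]),
        np.array([0.0, 0.0, -20.0]),
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        np.array([0.0, 0.0, -1.0]),
        0.5,
    )
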