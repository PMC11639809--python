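"""Numba kernel for the per-level Lucas-Kanade solve.

One call refines the flow of all points on one pyramid level: for each
point the template window and its gradients are sampled from the previous
frame (bilinear, clamped at borders), the 2x2 normal matrix inverted once,
and the flow updated by Newton iterations against the next frame until the
step falls below ``eps`` or ``max_iter`` is reached.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _bilinear(img, x, y):
    h, w = img.shape
    if x < 0.0:
        x = 0.0
    elif x > w - 1.0:
        x = w - 1.0
    if y < 0.0:
        y = 0.0
    elif y > h - 1.0:
        y = h - 1.0
    x0 = int(x)
    y0 = int(y)
    if x0 > w - 2:
        x0 = w - 2
    if y0 > h - 2:
        y0 = h - 2
    wx = x - x0
    wy = y - y0
    top = img[y0, x0] * (1.0 - wx) + img[y0, x0 + 1] * wx
    bot = img[y0 + 1, x0] * (1.0 - wx) + img[y0 + 1, x0 + 1] * wx
    return top * (1.0 - wy) + bot * wy


@njit(cache=True)
def lk_level(img_p, gx_img, gy_img, img_n, pts, flow, radius, max_iter, eps, min_det):
    """Refine ``flow`` (n, 2) in place for all ``pts`` (n, 2) on one level.

    Returns an int8 status per point: 1 ok, 0 window out of bounds,
    -1 normal matrix ill-conditioned.
    """
    n = pts.shape[0]
    h, w = img_p.shape
    win = 2 * radius + 1
    npix = win * win
    status = np.ones(n, dtype=np.int8)
    tmpl = np.empty(npix)
    gx = np.empty(npix)
    gy = np.empty(npix)
    for i in range(n):
        px = pts[i, 0]
        py = pts[i, 1]
        if px < radius or px > w - 1 - radius or py < radius or py > h - 1 - radius:
            status[i] = 0
            continue
        gxx = 0.0
        gxy = 0.0
        gyy = 0.0
        k = 0
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                sx = px + dx
                sy = py + dy
                tmpl[k] = _bilinear(img_p, sx, sy)
                a = _bilinear(gx_img, sx, sy)
                b = _bilinear(gy_img, sx, sy)
                gx[k] = a
                gy[k] = b
                gxx += a * a
                gxy += a * b
                gyy += b * b
                k += 1
        det = gxx * gyy - gxy * gxy
        if det <= min_det:
            status[i] = -1
            continue
        vx = flow[i, 0]
        vy = flow[i, 1]
        for _ in range(max_iter):
            bx = 0.0
            by = 0.0
            k = 0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    diff = tmpl[k] - _bilinear(img_n, px + dx + vx, py + dy + vy)
                    bx += gx[k] * diff
                    by += gy[k] * diff
                    k += 1
            ux = (gyy * bx - gxy * by) / det
            uy = (gxx * by - gxy * bx) / det
            vx += ux
            vy += uy
            if ux * ux + uy * uy < eps * eps:
                break
        flow[i, 0] = vx
        flow[i, 1] = vy
    return status
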