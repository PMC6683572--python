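"""Naive per-pixel reference implementation, independent of the package.

Pure-Python double loops that re-state the color measures and the labeling
rule from first principles.  The package's vectorized classification must
match this oracle bit-exactly; the oracle must therefore never import the
package's classify/color modules.
"""

FOREGROUND, IGNORED, BACKGROUND = 0, 1, 2


def ycbcr(px):
    r, g, b = px
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return (
        min(max(y, 0.0), 255.0),
        min(max(cb, 0.0), 255.0),
        min(max(cr, 0.0), 255.0),
    )


def measure(px, ch, metric):
    if metric == "rgb":
        return (
            (px[0] - ch[0]) ** 2
            + (px[1] - ch[1]) ** 2
            + (px[2] - ch[2]) ** 2
        )
    a = ycbcr(px)
    b = ycbcr(ch)
    return (a[1] - b[1]) ** 2 + (a[2] - b[2]) ** 2 + (a[0] - b[0]) ** 2 / 9


def min_measures(pixels, channels, metric):
    """Per-pixel minimum measure grid, explicit double loop."""
    out = []
    for row in pixels:
        out_row = []
        for px in row:
            px = (int(px[0]), int(px[1]), int(px[2]))
            best = None
            for ch in channels:
                d = measure(px, ch, metric)
                if best is None or d < best:
                    best = d
            out_row.append(best)
        out.append(out_row)
    return out


def labels_from_measures(min_inc, min_ign, tol, conflict="nearest"):
    """Apply the three-way decision rule; ``min_ign`` may be None."""
    t2 = tol * tol
    labels = []
    for yy in range(len(min_inc)):
        row = []
        for xx in range(len(min_inc[yy])):
            mi = min_inc[yy][xx]
            within_inc = mi < t2
            if min_ign is None:
                row.append(FOREGROUND if within_inc else BACKGROUND)
                continue
            mg = min_ign[yy][xx]
            within_ign = mg < t2
            if conflict == "nearest":
                fg = within_inc and (not within_ign or mi < mg)
            elif conflict == "ignore-wins":
                fg = within_inc and not within_ign
            elif conflict == "include-wins":
                fg = within_inc
            else:
                raise ValueError(conflict)
            if fg:
                row.append(FOREGROUND)
            elif within_ign:
                row.append(IGNORED)
            else:
                row.append(BACKGROUND)
        labels.append(row)
    return labels


def classify(pixels, include, ignore, tol, metric, conflict="nearest"):
    min_inc = min_measures(pixels, include, metric)
    min_ign = min_measures(pixels, ignore, metric) if ignore else None
    return labels_from_measures(min_inc, min_ign, tol, conflict)
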