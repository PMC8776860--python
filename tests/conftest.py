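import numpy as np
import pandas as pd
import pytest

from mxproximity.io import SlideCellTable


def make_slide(slide_id, targets=(), references=(), others=(),
               panel=("SOX10", "CD8"), area_mm2=1.0, nucleated=True):
    """Build a SlideCellTable from explicit centroid lists.

    ``targets`` carry the first panel marker, ``references`` the second,
    ``others`` none.
    """
    rows = []
    for prefix, pts, marks in (("t", targets, {panel[0]}),
                               ("r", references, {panel[1]}),
                               ("o", others, set())):
        for i, (x, y) in enumerate(pts):
            row = {"cell_id": f"{prefix}{i}", "x_um": float(x),
                   "y_um": float(y), "nucleated": nucleated}
            for m in panel:
                row[m] = m in marks
            rows.append(row)
    cols = ["cell_id", "x_um", "y_um", "nucleated", *panel]
    cells = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(
        {c: [] for c in cols})
    return SlideCellTable(slide_id, cells, panel, region_area_mm2=area_mm2)


def random_slide(rng, n_target=200, n_reference=200, width=1000.0,
                 height=1000.0, slide_id="rand"):
    t = np.column_stack([rng.uniform(0, width, n_target),
                         rng.uniform(0, height, n_target)])
    r = np.column_stack([rng.uniform(0, width, n_reference),
                         rng.uniform(0, height, n_reference)])
    return make_slide(slide_id, t, r, area_mm2=width * height / 1e6)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
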