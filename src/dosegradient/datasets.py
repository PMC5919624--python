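"""Bundled reference benchmark tables.

Two published benchmark datasets for the DGI arithmetic:

* ``multilayer_reference`` — surface areas and volumes of a 14-layer
  structure built by uniformly expanding an irregular ~2.5 cm^3 structure
  at exact 1-mm intervals on a clinical planning system, together with the
  DGI values computed over 1-, 2- and 3-layer gaps.  The ground truth for
  every gap is its physical width (1/2/3 mm).

* ``srs_reference`` — the isodose-level table of a 3-arc dynamic-arc SRS
  plan for a 3-cm-diameter spherical target prescribed 15 Gy (100% = 15 Gy,
  no renormalization; calculation interval 1%), with differential and
  cumulative DGI columns at 2-decimal report precision.  The source table
  prints the 24-30%, 50% and 90-121% rows; the cumulative column there was
  accumulated from the rounded differential values.

These are verification fixtures for the index arithmetic, not meshing
fixtures: the underlying structures are not published as coordinates.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["multilayer_reference", "srs_reference"]

_N = float("nan")

# layer, surface_area_mm2, volume_mm3, dgi_1mm, dgi_2mm, dgi_3mm
_MULTILAYER = [
    (0, 1477.332, 4099.663, _N, _N, _N),
    (1, 1802.676, 5778.131, 1.023454, _N, _N),
    (2, 2154.435, 7781.413, 1.012497, 2.027526, _N),
    (3, 2522.306, 10106.71, 0.994409, 2.001663, 3.003796),
    (4, 2920.762, 12842.98, 1.005416, 1.994630, 2.991402),
    (5, 3345.715, 15992.61, 1.005229, 2.006092, 2.985806),
    (6, 3789.611, 19550.83, 0.997355, 1.999247, 2.992473),
    (7, 4261.514, 23565.85, 0.997381, 1.991066, 2.985925),
    (8, 4768.102, 28178.60, 1.021692, 2.016372, 3.003763),
    (9, 5286.241, 33161.19, 0.991131, 2.009966, 2.999245),
    (10, 5829.997, 38702.98, 0.997063, 1.986088, 2.999972),
    (11, 6411.771, 44898.54, 1.012200, 2.006726, 2.991078),
    (12, 7006.067, 51577.42, 0.995523, 2.005980, 2.996383),
    (13, 7627.859, 58884.88, 0.998701, 1.992409, 2.999274),
]

# dose_pct, surface_area_mm2, volume_mm3, ddgi_mm, cdgi_mm  (dose_gy = 0.15*pct)
_SRS = [
    (24, 16497.6, 165740.9, 0.99, 17.26),
    (25, 15268.0, 150037.0, 0.87, 16.27),
    (26, 14272.0, 137215.8, 0.78, 15.40),
    (27, 13438.1, 126401.9, 0.73, 14.62),
    (28, 12682.9, 116848.6, 0.65, 13.89),
    (29, 12016.5, 108844.4, 0.58, 13.24),
    (30, 11416.7, 102008.5, 0.57, 12.66),
    (50, 6187.0, 44735.6, 0.18, 5.98),
    (90, 3722.9, 21025.7, 0.10, 1.13),
    (91, 3677.5, 20655.6, 0.11, 1.03),
    (92, 3628.4, 20248.4, 0.10, 0.92),
    (93, 3586.0, 19887.5, 0.11, 0.82),
    (94, 3537.9, 19486.2, 0.11, 0.71),
    (95, 3490.1, 19088.6, 0.10, 0.60),
    (96, 3444.6, 18728.2, 0.11, 0.50),
    (97, 3397.9, 18335.1, 0.11, 0.39),
    (98, 3346.7, 17949.4, 0.13, 0.28),
    (99, 3293.4, 17515.5, 0.15, 0.15),
    (100, 3235.7, 17035.3, 0.13, 0.00),
    (101, 3180.6, 16606.7, 0.15, _N),
    (102, 3124.0, 16144.7, 0.13, _N),
    (103, 3068.3, 15731.0, 0.15, _N),
    (104, 3009.2, 15284.3, 0.16, _N),
    (105, 2944.0, 14801.0, 0.18, _N),
    (106, 2876.2, 14290.8, 0.20, _N),
    (107, 2804.1, 13719.9, 0.18, _N),
    (108, 2732.5, 13226.9, 0.23, _N),
    (109, 2648.1, 12608.6, 0.25, _N),
    (110, 2556.7, 11946.2, 0.25, _N),
    (111, 2464.2, 11308.0, 0.31, _N),
    (112, 2356.9, 10557.6, 0.33, _N),
    (113, 2241.2, 9804.0, 0.39, _N),
    (114, 2109.2, 8944.8, 0.46, _N),
    (115, 1960.4, 8005.2, 0.54, _N),
    (116, 1792.9, 6993.9, 0.68, _N),
    (117, 1594.9, 5837.9, 0.83, _N),
    (118, 1365.5, 4612.7, 1.15, _N),
    (119, 1077.1, 3207.2, 1.60, _N),
    (120, 731.1, 1763.2, 2.29, _N),
    (121, 341.0, 536.3, _N, _N),
]

SRS_PRESCRIPTION_GY = 15.0
SRS_PTV_RADIUS_MM = 15.0


def multilayer_reference() -> pd.DataFrame:
    """The 14-layer uniform-expansion benchmark (1-mm intervals)."""
    return pd.DataFrame(
        _MULTILAYER,
        columns=["layer", "surface_area_mm2", "volume_mm3", "dgi_1mm", "dgi_2mm", "dgi_3mm"],
    )


def srs_reference() -> pd.DataFrame:
    """The SRS-plan isodose benchmark table (1% interval, 15 Gy = 100%).

    Rows between 31-49% and 51-89% are not published; ``ddgi_mm`` and
    ``cdgi_mm`` carry the 2-decimal printed values, NaN where absent.
    """
    df = pd.DataFrame(
        _SRS, columns=["dose_pct", "surface_area_mm2", "volume_mm3", "ddgi_mm", "cdgi_mm"]
    )
    df.insert(1, "dose_gy", df["dose_pct"] * SRS_PRESCRIPTION_GY / 100.0)
    return df


def srs_records(rows: pd.DataFrame | None = None):
    """SRS benchmark rows as :class:`IsodoseLevelRecord` objects."""
    from .dgc import IsodoseLevelRecord

    df = srs_reference() if rows is None else rows
    return [
        IsodoseLevelRecord(
            dose_pct=float(r.dose_pct),
            dose_gy=float(r.dose_gy),
            surface_area=float(r.surface_area_mm2),
            volume=float(r.volume_mm3),
        )
        for r in df.itertuples()
    ]
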