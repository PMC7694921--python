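"""Published provincial summary statistics for Jiangsu (2014–2018).

City-level raw data behind these summaries are not public; what *is*
published are province-level density tables, yearly efficiency means and
Malmquist summaries.  They are useful as recomposition inputs: the identities
this package implements (density = total/basis, SE = TE/PTE,
TFPC = TEC·TC, TEC = PTEC·SEC) must reproduce each printed cell from the
others at the printed precision.

A handful of printed Malmquist cells are internally inconsistent by one unit
in the last printed digit (flagged below); recomposition checks skip those.
"""

from __future__ import annotations

#: year -> (per-1000-person, per-km², total) for each primary resource.
PRIMARY_RESOURCE_DENSITIES: dict[int, dict[str, tuple[float, float, float]]] = {
    2014: {"institutions": (0.4020, 0.2985, 32000),
           "beds": (4.9283, 3.6594, 392293),
           "health_workers": (7.4070, 5.5000, 589598)},
    2015: {"institutions": (0.4003, 0.2978, 31925),
           "beds": (5.1857, 3.8583, 413612),
           "health_workers": (7.7601, 5.7737, 618945)},
    2016: {"institutions": (0.4017, 0.2998, 32135),
           "beds": (5.5394, 4.1334, 443100),
           "health_workers": (8.1786, 6.1027, 654210)},
    2017: {"institutions": (0.3990, 0.2989, 32037),
           "beds": (5.8514, 4.3825, 469805),
           "health_workers": (8.6286, 6.4626, 692794)},
    2018: {"institutions": (0.4130, 0.3102, 33253),
           "beds": (6.1051, 4.5851, 491522),
           "health_workers": (9.1826, 6.8964, 739294)},
}

#: yearly mean radial efficiencies: year -> (TE mean, PTE mean, SE mean).
EFFICIENCY_MEANS: dict[int, tuple[float, float, float]] = {
    2014: (0.931, 0.995, 0.936),
    2015: (0.931, 0.998, 0.932),
    2016: (0.929, 0.999, 0.930),
    2017: (0.929, 0.998, 0.931),
    2018: (0.947, 0.993, 0.953),
}

#: Malmquist summary by adjacent year pair: (TEC, TC, PTEC, SEC, TFPC).
MPI_BY_YEAR: dict[str, tuple[float, float, float, float, float]] = {
    "2014-2015": (0.999, 0.993, 1.007, 0.992, 0.991),
    "2015-2016": (0.998, 0.994, 0.990, 1.008, 0.992),
    "2016-2017": (1.001, 0.992, 0.998, 1.004, 0.993),
    "2017-2018": (1.020, 0.949, 0.988, 1.033, 0.968),
}

#: Malmquist summary by city: (TEC, TC, PTEC, SEC, TFPC).  Zhenjiang's
#: published row lacks one cell; TEC/TC are as printed and PTEC/SEC carry
#: None.
MPI_BY_CITY: dict[str, tuple[float | None, ...]] = {
    "Nanjing": (1.000, 1.058, 1.000, 1.000, 1.058),
    "Wuxi": (0.958, 1.006, 0.959, 0.998, 0.964),
    "Changzhou": (1.000, 0.997, 1.000, 1.000, 0.997),
    "Suzhou": (1.000, 0.979, 1.000, 1.000, 0.979),
    "Zhenjiang": (1.011, 1.000, None, None, 1.010),
    "Nantong": (1.000, 0.992, 1.000, 1.000, 0.992),
    "Yangzhou": (1.047, 0.991, 1.000, 1.047, 1.038),
    "Taizhou": (1.024, 1.000, 1.000, 1.024, 1.023),
    "Xuzhou": (1.000, 0.967, 1.000, 1.000, 0.967),
    "Lianyungang": (1.001, 0.930, 0.974, 1.028, 0.931),
    "Huaian": (1.011, 1.009, 1.010, 1.001, 1.021),
    "Yancheng": (1.008, 0.940, 1.000, 1.008, 0.948),
    "Suqian": (1.000, 0.901, 1.000, 1.000, 0.901),
    "Mean": (1.004, 0.982, 0.996, 1.009, 0.986),
}

#: published cells that disagree with their own row's product by one unit of
#: the printed 3-dp precision; recomposition checks exclude them.
INCONSISTENT_TFPC_CELLS = frozenset({"2014-2015", "Taizhou", "Huaian", "Zhenjiang"})
INCONSISTENT_TEC_CELLS = frozenset({"2016-2017", "2017-2018", "Wuxi", "Mean", "Zhenjiang"})


def implied_basis_totals(year: int) -> tuple[float, float]:
    """Implied province population (thousands) and area (km²) for one year.

    Each printed density cell constrains total = density·basis to a 4-dp
    rounding interval; intersecting the three resources' intervals pins the
    basis total.  Returns the midpoint of each intersection.
    """
    row = PRIMARY_RESOURCE_DENSITIES[year]
    out = []
    for pos in (0, 1):  # per-1000-person column, then per-km² column
        lo = max(tot / (cells[pos] + 5e-5) for cells in row.values() for tot in [cells[2]])
        hi = min(tot / (cells[pos] - 5e-5) for cells in row.values() for tot in [cells[2]])
        if lo > hi:
            raise ValueError(f"inconsistent printed densities for {year}")
        out.append((lo + hi) / 2)
    return out[0], out[1]
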