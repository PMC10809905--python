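"""Published summary tables for the 211-line yardlong bean RIL population.

These are the printed per-chromosome map summary and trait descriptive
statistics for the high-density bin map this pipeline re-implements. The raw
resequencing data behind them is not deposited, so these printed numbers act
as inputs: the arithmetic layer (totals, averages, percentage conventions)
is recomputed from them and checked against the printed derived values.
"""

from __future__ import annotations

import io

import pandas as pd

# Per chromosome: physical chromosome length (Mb), bin count, summed bin
# physical length (Mb), summed gap length (Mb), summed genetic distance (cM).
_MAP_TABLE_TSV = """\
chrom	chrom_mb	n_bins	bin_sum_mb	gap_sum_mb	cm_sum
1	42.13	244	32.88	9.25	185.36
2	33.91	95	24.40	9.51	94.88
3	65.29	319	48.66	16.64	213.07
4	42.73	165	26.37	16.36	140.55
5	48.75	262	33.43	15.32	202.16
6	34.46	53	31.55	2.91	39.98
7	40.88	222	24.01	16.86	126.83
8	38.36	156	25.00	13.36	103.41
9	43.93	244	32.67	11.26	167.11
10	41.33	136	39.48	1.84	35.69
11	41.68	188	30.73	10.95	114.51
"""

MAP_TABLE: pd.DataFrame = pd.read_csv(io.StringIO(_MAP_TABLE_TSV), sep="\t")

#: the printed totals row; the Mb/cM entries carry more precision than the
#: half-up-rounded per-chromosome rows (which sum 0.01 short), so derived
#: averages are taken from here while the integer bin count is summed.
MAP_TOTALS = {
    "chrom_mb": 473.46,
    "n_bins": 2084,
    "bin_sum_mb": 349.19,
    "gap_sum_mb": 124.27,
    "cm_sum": 1423.56,
}

#: counts of bins / gaps / adjacent distances in the reported length classes
BIN_LENGTH_COUNTS = {"below_100kb": 1350, "above_1100kb": 51}
GAP_LENGTH_COUNTS = {"below_10kb": 1110, "above_100kb": 259}
ADJACENT_CM_COUNTS = {"below_0_5": 1640, "above_6_0": 19}

# Trait descriptive rows: parents P1 ('SZ41') and P2 ('S1419') and the RIL
# population mean, by environment (two field seasons).
_TRAIT_TABLE_TSV = """\
trait	environment	p1	p2	ril_mean
ANT	2020	91.55	8.78	68.88
ANT	2021	114.99	10.78	67.89
VE	2020	89.39	63.86	89.96
VE	2021	94.08	67.45	65.59
TSP	2020	1.84	0.39	0.77
TSP	2021	1.13	0.31	0.83
PL	2020	61.52	44.21	56.11
PL	2021	64.14	46.85	40.40
HSW	2020	10.99	16.35	16.30
HSW	2021	16.57	18.58	18.19
SL	2020	9.84	9.98	11.19
SL	2021	9.19	8.37	9.61
SW	2020	5.77	5.74	6.26
SW	2021	5.15	5.08	5.21
"""

TRAIT_TABLE: pd.DataFrame = pd.read_csv(io.StringIO(_TRAIT_TABLE_TSV), sep="\t")
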