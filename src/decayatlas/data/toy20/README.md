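# toy20 — hand-built 20-gene filter oracle

All library totals are 10^9 reads, so FPKM = counts / length_bp exactly and
every expected value below can be checked by mental arithmetic.  One sample
per table.  All comparisons are strict `<` at the printed thresholds.

## Minimum-expression filter (exonic FPKM < 0.00015 removed)

| gene | exon bp | counts | FPKM     | outcome                         |
|------|---------|--------|----------|---------------------------------|
| g02  | 10000   | 1      | 0.0001   | removed                         |
| g03  | 1000    | 0      | 0        | removed                         |
| g04  | 20000   | 3      | 0.00015  | retained (boundary, strict `<`) |
| g05  | 100000  | 2      | 0.00002  | removed                         |
| rest | —       | —      | ≥ 0.0001 | retained                        |

**Retained: 17 of 20** (removed: g02, g03, g05).

## Intron quality filter (intron FPKM < 0.01 OR intron length < 30 bp)

| gene | intron bp | counts | intron FPKM | outcome                         |
|------|-----------|--------|-------------|---------------------------------|
| g06  | 10        | 5      | 0.5         | eliminated (length)             |
| g07  | 29        | 1      | 0.0345      | eliminated (length)             |
| g08  | 0         | 0      | undefined   | eliminated (no intron)          |
| g09  | 1000      | 5      | 0.005       | eliminated (FPKM)               |
| g10  | 1000      | 10     | 0.01        | retained (boundary, strict `<`) |
| g11  | 1000      | 9      | 0.009       | eliminated (FPKM)               |
| rest | ≥ 500     | —      | ≥ 0.02      | retained                        |

**Retained: 15 of 20** (eliminated: g06, g07, g08, g09, g11).

## RIP dual filter (excluded iff input AND pulldown FPKM < 0.1; input = 0 undefined)

| gene | input FPKM | RIP FPKM | enrichment | outcome                 |
|------|------------|----------|------------|-------------------------|
| g12  | 0.05       | 0.05     | —          | excluded (both < 0.1)   |
| g13  | 0.05       | 0.5      | 10.0       | kept (one value ≥ 0.1)  |
| g14  | 0          | 0.2      | —          | excluded (input 0)      |
| g15  | 0          | 0        | —          | excluded                |
| g19  | 0.1        | 0.1      | 1.0        | kept (boundary)         |
| rest | ≥ 0.1      | —        | defined    | kept                    |

**Retained: 17 of 20** (excluded: g12, g14, g15).

## Bound calls (enrichment > 1.5, strict)

Bound: g01 (3.0), g06 (2.0), g08 (4.0), g10 (2.0), g13 (10.0), g17 (1.6) — **6 genes**.
g16 sits exactly at 1.5 and is NOT bound.
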