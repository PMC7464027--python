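# Bin boundary tables for the subdivided surface-area descriptors.
#
# Each family partitions the per-atom approximate accessible van der Waals
# surface areas by an atomic property.  Bin i of a boundary list
# [b0, b1, ..., bm] covers the half-open interval [b_{i-1}, b_i), with
# bin 0 = (-inf, b0) and bin m+1 = [bm, +inf).
#
# slogp / smr boundaries follow Labute's published subdivision of the
# Wildman-Crippen atomic logP and molar-refractivity contributions, which is
# the subdivision the fitted model coefficients assume.
slogp:
  boundaries: [-0.4, -0.2, 0.0, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4]
smr:
  boundaries: [1.29, 1.82, 2.24, 2.45, 2.75, 3.05, 3.63, 3.8, 4.0]
# peoe bins are generated, not listed: signed bins of width 0.05 in partial
# charge.  "+k" covers [0.05k, 0.05(k+1)) for k in 0..5 and [0.30, inf) for
# k = 6; "-k" covers [-0.05(k+1), -0.05k) for k in 0..5 and (-inf, -0.30)
# for k = 6, so "-0" is [-0.05, 0).
peoe:
  width: 0.05
  max_bin: 6
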