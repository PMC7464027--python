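# Frozen PLS QSAR equations for AChE and BACE-1 pIC50 prediction.
# AT/BT are the training-set fits; AF/BF the full-data-set fits.
# These coefficients are data, not code: prediction is
#   pIC50 = intercept + sum(coefficient * descriptor).
models:
  AT:
    target: AChE
    provenance: training-set PLS fit (n = 50)
    intercept: -0.92791
    terms:
      BCUT_SLOGP_3: 2.34847
      reactive: -0.14990
      PEOE_VSA+1: -0.00355
      PEOE_VSA-3: -0.00514
      SlogP_VSA2: -0.00219
      SMR_VSA2: -0.00447
  AF:
    target: AChE
    provenance: full-data-set PLS fit (n = 72)
    intercept: -1.00890
    terms:
      BCUT_SLOGP_3: 2.38027
      reactive: -0.11002
      PEOE_VSA+1: -0.00391
      PEOE_VSA-3: -0.00480
      SlogP_VSA2: -0.00202
      SMR_VSA2: -0.00387
  BT:
    target: BACE-1
    provenance: training-set PLS fit (n = 150)
    intercept: 1.26826
    terms:
      petitjean: 0.87076
      BCUT_PEOE_1: 6.37086
      a_ICM: 3.30481
      chiral_u: -0.47753
      rings: 0.08513
      a_nN: 0.15746
      PEOE_VSA-0: 0.00608
      PEOE_VSA-6: 0.02183
      logS: -0.25952
      SlogP_VSA3: 0.00893
      SlogP_VSA5: 0.00944
  BF:
    target: BACE-1
    provenance: full-data-set PLS fit (n = 215)
    intercept: 1.01351
    terms:
      petitjean: 0.59775
      BCUT_PEOE_1: 4.85517
      a_ICM: 3.13351
      chiral_u: -0.50839
      rings: 0.02540
      a_nN: 0.16067
      PEOE_VSA-0: 0.00577
      PEOE_VSA-6: 0.01771
      logS: -0.26227
      SlogP_VSA3: 0.00920
      SlogP_VSA5: 0.01101
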