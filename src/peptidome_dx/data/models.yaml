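# Default candidate model space for exposure model building.
#
# Every model pairs one base exposure term with a covariate subset of size
# at most max_covariates. With 5 bases and C(9,0)+C(9,1)+C(9,2) = 46
# covariate subsets this space holds 230 models. The originally reported
# model count (237) is not exactly reconstructible from its description;
# the space here approximates it and both the pool and the subset size are
# configurable.
bases:
  - logInhEC
  - logResEC
  - logSC
  - logInhResEC
  - logSumExp
covariates:
  - logIL6
  - logCCL2
  - logTNFalpha
  - logVCAM
  - logICAM
  - age_bin
  - duration_bin
  - sex
  - solvent_current
max_covariates: 2
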