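# Same workflow with the calibration step inserted after the HMM build.
initial: n_emma
nodes:
  n_emma: emma
  n_build: ehmmbuild
  n_calibrate: ehmmcalibrate
  n_emit: ehmmemit
  n_show: showseq
edges:
  - {src: n_emma, dst: n_build}
  - {src: n_build, dst: n_calibrate}
  - {src: n_calibrate, dst: n_emit}
  - {src: n_emit, dst: n_show}
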