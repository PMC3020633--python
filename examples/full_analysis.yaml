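# Full parametric-bootstrap analysis: all 15 builtin models of
# Limenitis history against the observed deep-coalescence statistics.
# Run with:  coalboot run --config examples/full_analysis.yaml
models: all
nreps: 2000
seed: 1
out_dir: coalboot_out
# observed summed deep coalescences on the two rival species trees
# (arthemis+astyanax sister vs arizonensis+astyanax sister)
observed_dc_R: 93
observed_dc_MM: 108
# outgroup divergence times (years) may be overridden, e.g.:
# outgroup_times:
#   lorquini: 1.5e6
#   weidemeyerii: 2.5e6
#   archippus: 3.5e6
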