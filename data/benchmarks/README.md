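# Benchmark datasets

The benchmark-reproduction test (`tests/test_acceptance.py::test_benchmark_reproduction`)
runs PFD-DPC on the six classic shape benchmarks at their published
parameters and checks the published AMI/ARI/FMI scores. The files are not
redistributed with this repository; download them from

    https://github.com/sdnu-ZhuangHui/Datasets-of-PFD-DPC

and place them here as plain-text tables (features first, integer label
last, whitespace- or comma-delimited), named:

    jain.txt  spiral.txt  pathbased.txt  r15.txt  aggregation.txt  dim512.txt

Without these files the test fails with a message naming the missing
datasets. Every other test runs on seeded synthetic stand-ins generated by
`pfdcluster.datasets` and needs no downloads.
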