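# Reference structures

Experimental PDB files used by the validation tests in
`tests/test_acceptance.py`. They are not shipped with the repository;
place `<ID>.pdb` files here (e.g. `1CAA.pdb`) to run those tests
offline, otherwise the tests attempt a download from the RCSB.
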