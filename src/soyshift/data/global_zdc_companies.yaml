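# Traders with global voluntary zero-deforestation pledges (soy supply
# chain), applied here as if implemented in the 2011 benchmark year.
companies:
  - ADM
  - Amaggi
  - Bunge
  - Cargill
  - Louis Dreyfus
  - Cofco
  - Glencore
  - Denofa do Brazil
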