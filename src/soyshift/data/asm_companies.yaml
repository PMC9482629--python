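# Amazon Soy Moratorium signatories that export soybeans from the Amazon.
# Editable configuration data: company names are inputs, not code.
companies:
  - Abc Industria
  - ADM
  - Amaggi
  - Bunge
  - Cargill
  - Louis Dreyfus
  - Seara
  - Fiagril
  - Nidera
  - Noble
  - Cofco
  - Baldo
  - Imcopa
  - Agrex
  - CHS
  - Coamo
  - Engelhart CTP
  - Gavilon
  - Glencore
  - Invivo
  - Marubeni
  - Multigrain
  - Nova Agri
  - Olam
  - Perdue
  - Sodrugestvo
  - Timbro
  - Selecta
# Signatories with no soy exports from the Amazon (kept for reference):
non_exporting:
  - Binatural
  - JBS
  - Oleos Menu
  - Agribrasil
  - Culturale
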