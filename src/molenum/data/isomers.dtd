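<!ELEMENT enumeration (formula*)>
<!ELEMENT formula (isomer*)>
<!ATTLIST formula name CDATA #REQUIRED>
<!ELEMENT isomer (stereoisomer*)>
<!ATTLIST isomer
  smiles CDATA #REQUIRED
  n_tet CDATA #REQUIRED
  n_ct CDATA #REQUIRED>
<!ELEMENT stereoisomer EMPTY>
<!ATTLIST stereoisomer
  id CDATA #REQUIRED
  smiles CDATA #REQUIRED
  n_tet CDATA #REQUIRED
  n_ct CDATA #REQUIRED
  enantiomer CDATA #IMPLIED>
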