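# Maps plate carbon sources to the polysaccharide substrate whose degradative
# machinery they report on. Di-/oligosaccharides map to the polymer they derive
# from. Editable; pass a custom table to override.
carbon_source	substrate
beechwood xylan	xylan
guar gum	mannan
apple pectin	pectin
citrus pectin	pectin
soluble starch	starch
maltose	starch
inulin	inulin
sucrose	inulin
cellulose	cellulose
cellobiose	cellulose
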