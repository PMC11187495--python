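# Salt / counter-ion tokens dropped during ingredient-name normalization.
# One token per line; matching is exact-token after case folding, so
# e.g. "mononitrate" (part of the ingredient identity for nitrates) is
# deliberately NOT listed.  Edit or extend per deployment.
hydrochloride
dihydrochloride
sodium
disodium
potassium
calcium
magnesium
sulfate
sulphate
mesylate
mesilate
maleate
tartrate
bitartrate
citrate
fumarate
succinate
acetate
besylate
besilate
tosylate
tosilate
phosphate
hydrobromide
bromide
chloride
oxalate
lactate
gluconate
carbonate
nitrate
hemihydrate
monohydrate
dihydrate
trihydrate
hydrate
anhydrous
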