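generic,category
brolucizumab,ocular
pegcetacoplan,ocular
voretigene neparvovec,ocular
ocriplasmin,ocular
pilocarpine,ocular
faricimab,ocular
aflibercept,ocular
ranibizumab,ocular
brimonidine,ocular
latanoprost,ocular
lifitegrast,ocular
crizotinib,oncology
binimetinib,oncology
trametinib,oncology
encorafenib,oncology
bevacizumab,oncology
dabrafenib,oncology
dexamethasone,hormonal
fluocinolone acetonide,hormonal
difluprednate,hormonal
triamcinolone,hormonal
corticotropin,hormonal
raloxifene,hormonal
finasteride,hormonal
clofazimine,antimicrobial
terbinafine,antimicrobial
ciprofloxacin,antimicrobial
voriconazole,antimicrobial
cyclosporine,immunological
siponimod,immunological
fingolimod,immunological
oxymetazoline,other
pentosan polysulfate,other
patisiran,other
tadalafil,other
sildenafil,other
inotersen,other
botulinum toxin type a,other
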