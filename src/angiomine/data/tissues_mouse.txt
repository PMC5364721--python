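bone
bone marrow
brain
eye
heart
intestine
kidney
liver
lung
lymph node
muscle
pancreas
skin
spleen
stomach
testis
thymus
thyroid
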