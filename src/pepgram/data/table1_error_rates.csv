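,gvgg1,gvgg2,gvgg3,gtgg1,gtgg2,gtgg3,gfgg1,gfgg2,gfgg3,gtg1,gtg2,gvg1,gvg2,vgg1,vgg2,mgg1,mgg2,fgg1,fgg2
gvgg1,,0.2,0.2,0.4,0.3,0.2,0.7,0.3,0.2,0.4,0.1,0.4,0.1,0.1,0.1,0.1,0.1,0.1,0.1
gvgg2,0.2,,0.2,0.3,0.6,0.2,0.3,0.7,0.2,0.3,0.1,0.2,0.1,0.3,0.1,0.2,0.1,0.3,0.1
gvgg3,0.2,0.2,,0.2,0.2,0.6,0.2,0.2,0.7,0.2,0.3,0.1,0.3,0.2,0.3,0.0,0.3,0.1,0.3
gtgg1,0.4,0.3,0.2,,0.3,0.2,0.5,0.3,0.2,0.5,0.1,0.3,0.1,0.2,0.1,0.1,0.1,0.2,0.1
gtgg2,0.3,0.6,0.2,0.3,,0.3,0.3,0.7,0.2,0.3,0.2,0.3,0.2,0.4,0.2,0.2,0.1,0.3,0.2
gtgg3,0.2,0.2,0.6,0.2,0.3,,0.2,0.2,0.7,0.2,0.4,0.1,0.4,0.2,0.3,0.1,0.3,0.1,0.4
gfgg1,0.7,0.3,0.2,0.5,0.3,0.2,,0.3,0.2,0.4,0.1,0.4,0.1,0.2,0.1,0.1,0.1,0.2,0.1
gfgg2,0.3,0.7,0.2,0.3,0.7,0.2,0.3,,0.2,0.2,0.1,0.2,0.1,0.4,0.1,0.3,0.1,0.4,0.1
gfgg3,0.2,0.2,0.7,0.2,0.2,0.7,0.2,0.2,,0.2,0.4,0.1,0.4,0.2,0.4,0.1,0.3,0.1,0.4
gtg1,0.4,0.3,0.2,0.5,0.3,0.2,0.4,0.2,0.2,,0.1,0.4,0.1,0.2,0.1,0.1,0.1,0.2,0.1
gtg2,0.1,0.1,0.3,0.1,0.2,0.4,0.1,0.1,0.4,0.1,,0.1,0.6,0.2,0.5,0.0,0.4,0.2,0.5
gvg1,0.4,0.2,0.1,0.3,0.3,0.1,0.4,0.2,0.1,0.4,0.1,,0.1,0.2,0.1,0.1,0.1,0.2,0.1
gvg2,0.1,0.1,0.3,0.1,0.2,0.4,0.1,0.1,0.4,0.1,0.6,0.1,,0.2,0.6,0.1,0.5,0.2,0.6
vgg1,0.1,0.3,0.2,0.2,0.4,0.2,0.2,0.4,0.2,0.2,0.2,0.2,0.2,,0.2,0.3,0.1,0.6,0.2
vgg2,0.1,0.1,0.3,0.1,0.2,0.3,0.1,0.1,0.4,0.1,0.5,0.1,0.6,0.2,,0.1,0.3,0.1,0.6
mgg1,0.1,0.2,0.0,0.1,0.2,0.1,0.1,0.3,0.1,0.1,0.0,0.1,0.1,0.3,0.1,,0.0,0.4,0.1
mgg2,0.1,0.1,0.3,0.1,0.1,0.3,0.1,0.1,0.3,0.1,0.4,0.1,0.5,0.1,0.3,0.0,,0.2,0.4
fgg1,0.1,0.3,0.1,0.2,0.3,0.1,0.2,0.4,0.1,0.2,0.2,0.2,0.2,0.6,0.1,0.4,0.2,,0.2
fgg2,0.1,0.1,0.3,0.1,0.2,0.4,0.1,0.1,0.4,0.1,0.5,0.1,0.6,0.2,0.6,0.1,0.4,0.2,
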