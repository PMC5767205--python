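cycle,hysteresis,se
91-49-17-91,6.7,0.4
91-17-45-91,-9.9,0.6
91-96-46-49-91,-3.7,0.5
96-98-46-96,4.2,0.4
91-96-98-91,4.9,0.5
76-12-41-M1-84-76,1.2,0.7
76-12-77-82-84-76,-0.4,0.4
76-12-41-38-10-76,-5.1,0.8
76-85-88-76,4.5,0.4
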