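/root/pkg/src/plvnetmontage.pyvalidation.py__init__.pypipeline.pypreprocess.pyconnectivity.pyrecording.py                                       stats.py�9�,�R��!?��         �   �������?5A�!?��         �   ~������C��!?��         atlas.py-�ܾ'�2�!?��         �   1���l��L�!?��         bands.py�x���6�!?��         �   ����I�2��
�q�!?��         cli.py��ۃ~�����!?��          �   ����>@��G�tH�!?��          synth.pyD�_�7�)�!?��         �   N����R�!�n̹!?��         �   $����/��eĹ��!?��         graph.py�V���%�h�!?��          66D7:A+Iz7~�66D7:A+Iz7~���� �   ��������      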